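# Methods

## Model and assumptions

Decomposition of a dilute metabolite in water is treated as
pseudo-first-order: water is in vast excess, so its concentration folds
into the rate constant and k = ln 2 / t½. Rates from concentration time
courses are extracted by ordinary least squares on ln C vs t rather than
nonlinear exponential fitting — deterministic, exact on noiseless
exponentials, and consistent with the assumption that measurement noise is
multiplicative (Gaussian in ln C). Series containing zero or negative
concentrations are rejected outright; silently truncating them would bias
the slope. A non-decaying series yields a non-positive rate, reported
rather than raised, so callers can decide its fate.

Temperature dependence is a single Arrhenius law per metabolite,
ln k = b/T + a with b = −Ea/R (R = 8.314 J mol⁻¹ K⁻¹), fitted by ordinary
least squares in (1/T, ln k) space. Data from multiple studies of the same
metabolite are pooled by plain concatenation with equal weights: each
published point counts once, and study identity is carried as provenance
only. Weighted least squares is deliberately not offered — per-point error
estimates are rarely comparable across studies, and equal weighting keeps
the procedure reproducible from the numbers papers actually print. The fit
requires at least three points at three distinct temperatures: the minimum
for a slope, an intercept and one residual degree of freedom, and the
inclusion rule the pipeline applies to every study.

Inference on the fitted line is the classical *mean-response* confidence
band,

    ln k̂(T) ± t(p, n−2) · s · √(1/n + (1/T − m)²/Sxx),

s² = RSS/(n−2), m the mean of 1/T, Sxx the sum of squared deviations of
1/T. The two readings that matter here:

* *p* follows the two-tailed (`TINV`) convention: it is the total tail
  mass, so the band covers the central 1−p probability and smaller p means
  a wider band.
* The band is for the **mean** of hypothetical replicate experiments, not
  for a single new observation. The stability question — "what would the
  average of many decomposition experiments find?" — is a question about
  the mean, so the (wider) new-observation prediction band is not used.

Extrapolation beyond the fitted temperature range is permitted (it is
often unavoidable when the target rate sits outside the measured range)
but flagged per point in every curve. Pooling data from non-replicate
experiments stretches the band's formal interpretation: the band is then a
quantitative index of cross-study consistency under the working assumption
that the studies sample a common super-population of experiments. When
that assumption fails, the band widens and the downstream classification
lands in "uncertain" — which is the behaviour we want.

## Stability confidence and classification

For a target half-life t½\*, the target rate is k\* = ln 2/t½\* and the
stability confidence at temperature T is the Student-t tail probability

    C(T) = F_t[(ln k\* − ln k̂(T)) / SE(T); n−2],

evaluated over a 1 K grid on 300–640 K. The window brackets the regime of
interest: below ~300 K sterile aqueous solutions keep complex biochemicals
for months to years, and near water's critical temperature all biological
matter chars within seconds, so nothing outside the window is informative.
The 1 K step is far below any band width the data can support; curves are
linear between grid points wherever interpolation is needed.

An equivalent grid-search formulation — sweep the two-tailed probability
p over 0.005…1 in steps of 0.005, find the p whose band boundary touches
ln k\*, and convert to a one-sided confidence (1 − p/2 above the centre,
p/2 below, 0.5 at p = 1 from either side) — is retained as an independent
oracle. The production path is the closed-form t-CDF: identical to within
half a grid step, faster, and free of grid artefacts.

Summary statistics per metabolite:

* **t50** — the temperature of the first downward crossing of C(T) = 0.5,
  linearly interpolated between grid points. Curves from downward-sloping
  fits are monotone (see *Numerical choices*), so the first crossing is
  the only one; if the curve starts below 0.5 or never reaches it, t50 is
  absent with a machine-readable reason rather than an error.
* **Classification** at a reference temperature (default 420 K) and
  confidence threshold (default 0.95): *stable* if C_long(420 K) ≥ 0.95.
  Otherwise the long-target curve's shape decides: *labile* if the curve
  is decisive — spanning ≥ 0.95 down to ≤ 0.05 inside the window with the
  0.9 → 0.1 drop completed within 100 K — else *uncertain*. The 100 K
  steepness span is a heuristic for a qualitative steep/shallow
  distinction; it cleanly separates the two canonical regimes (an exact
  fit's step curve vs the discrepant-study fixture) and is configurable.
* **Histogram** of t50 values in 10 K bins anchored at 300 K, labelled by
  the bin's lower edge (a t50 of 309.9 K falls in bin "300"); metabolites
  without a t50 are tallied separately.

Target half-lives are interpreted in seconds throughout. The built-in
class registry (amino acids 200/20 s, sugars 600/60 s, nucleotides
100/10 s, …) is an overridable default; its lipids row (long 500 s, short
5000 s) is inverted relative to every other class but is shipped as
published, since "short" and "long" are labels for two alternative
scenarios, not an ordering the code relies on.

## Pressure and Q10

Pressure acts through the activation volume ΔV‡ (cm³/mol). For hydrolysis
of uncharged species the package uses an empirical quadratic in
x = ΔP·ΔV‡ (atm·cm³/mol): ln(k_low/k_high) = −1.562·10⁻¹¹x² − 4.18·10⁻⁵x.
The API returns the reciprocal k_high/k_low — the speed-up under the
pressure increase — so positive ΔP·ΔV‡ gives a factor above 1. Two
conventions to note: ΔP is the literal pressure difference supplied by the
caller (no gauge-pressure assumption), and the quadratic term breaks the
naive antisymmetry, factor(ΔP, ΔV)·factor(ΔP, −ΔV) ≠ 1. At ΔP = 217 atm
(atmospheric to the critical pressure of water) and |ΔV‡| ≤ 20 the factor
stays within ±20%; at ΔP = 1100 atm (deep-ocean trench) and ΔV‡ = 20 the
model evaluates to ≈ 2.53 — pressure is a minor effect next to
temperature either way.

Q10, the rate ratio across a 10 K rise, comes directly from a fit:
Q10(T) = exp(b·(1/(T+10) − 1/T)). It composes exactly (two 10 K steps
equal the 20 K ratio) and decreases with temperature for positive Ea.
Aggregation across a metabolite set is a plain arithmetic mean of per-fit
values.

## Synthetic data: what it does and does not emulate

The generator draws ln k_ij = lnA − Ea/(R·T_ij) + β_i + ε_ij with
β_i ~ N(0, study_bias_sd²) per study and ε_ij ~ N(0, residual_sd²) per
point — exactly the structure the analysis assumes, plus the one violation
the analysis is meant to detect (study-level intercept offsets). Noise
lives in ln k space, matching the fitting space and keeping rates
positive. Every study has ≥ 3 distinct temperatures by construction, and
all randomness flows from explicit integer seeds through local numpy
generators.

Defaults used across the test suite reflect realistic literature-scale
data: residual scatter σ_lnk ≈ 0.05–0.3 (clean modern kinetics to noisy
replotted data), activation energies 60–160 kJ/mol, 3–8 points per study
over 40–150 K spans. The discrepant-study fixture places two concordant
3-point studies on the true line (Ea = 120 kJ/mol, lnA = 28,
σ_lnk = 0.08) and a third 4-point study offset by −4 ln units at higher
temperatures — a fixed, named offset, not a random draw — which flattens
the pooled slope and inflates RSS enough to land the classification in
"uncertain", while the concordant pair alone stays steep.

What the generator does **not** emulate: temperature-dependent mechanism
changes (curvature in the Arrhenius plot), slope (activation-energy)
biases between studies, non-Gaussian or heteroscedastic noise, censored
or detection-limited measurements, and errors in temperature itself.
Passing tests therefore certify the statistical machinery under its own
assumptions; they do not certify that real literature data satisfy those
assumptions.

## Numerical choices

* Student-t quantiles and CDFs come from `scipy.stats.t`; no lookup
  tables.
* An exact fit (RSS = 0) gives a degenerate zero-width band; the
  confidence is then a hard step (1 below the crossing, 0 above, 0.5 at
  equality) rather than an error.
* Monotonicity of confidence curves holds to a tolerance of 1e−5: deep in
  the saturated tails (confidence within ~1e−3 of 0 or 1, far outside the
  data, few degrees of freedom) the band's leverage growth can raise the
  t-CDF by ~1e−6 per kelvin step. The effect is orders of magnitude below
  any decision threshold and is absorbed rather than clipped.
* Crossing detection takes the *first* downward crossing and linear
  interpolation between the bracketing grid points; an exact hit on a
  grid point returns that temperature.
* Temperatures are kelvin everywhere internally; Celsius is accepted only
  at the I/O boundary (flag) and printed alongside kelvin in reports.
  A (250, 700) K sanity window on inputs catches unit mistakes early.
* Pipeline outputs are a pure function of input bytes and configuration;
  CSV serialisation uses shortest-repr floats, which round-trip losslessly.

## Problem sizes

The statistical checks run at the scale the claims are stated for: band
calibration uses 2000 Monte-Carlo replicates of n = 30 points with
σ_lnk = 0.2 and no study bias (coverage of the nominal 95% band expected
in 0.93–0.97); the closed-form/grid-sweep equivalence sweeps 50
randomized fits across all 341 grid temperatures. Both complete in
seconds.

## Known limitations

* Equal-weight pooling treats non-replicate studies as replicates; the
  resulting bands are indices of consistency, not calibrated frequentist
  intervals, when studies disagree systematically. A mixed-effects model
  would be the natural next step and is out of scope here.
* Single-mechanism Arrhenius extrapolation is unreliable when different
  decomposition channels dominate at different temperatures; the
  extrapolation flags mark where this risk applies but cannot detect it.
* The labile/uncertain boundary is a heuristic on curve shape; borderline
  curves near the 100 K span threshold can flip with modest data changes.
* The pressure model is an empirical fit for uncharged-species hydrolysis
  in water; it does not extend to ionic mechanisms or extreme pressures.
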