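# thermokin

Kinetic meta-analysis of metabolite decomposition in hot water: how hot can
an environment get before the small molecules of metabolism fall apart
faster than a cell could plausibly replace them?

`thermokin` turns per-study decomposition measurements — first-order rate
constants, half-lives, or raw concentration time courses — into:

* pooled **Arrhenius fits** of ln *k* on 1/*T* with mean-response
  confidence bands,
* **stability-confidence curves**: the confidence, as a function of
  temperature, that a metabolite's mean decomposition rate stays below the
  rate implied by a target half-life,
* per-metabolite **classification** (stable / labile / uncertain) against
  a reference temperature, plus *t50* summaries and histograms,
* **pressure** (activation-volume) and **Q10** corrections,
* a **synthetic-data generator** with known ground truth (including
  study-level systematic offsets) so the whole pipeline is testable
  without any external data.

## The model

Decomposition of a dilute metabolite M in water is pseudo-first-order,
so k = ln 2 / t½, and temperature dependence follows the Arrhenius law:

```
ln k = b·(1/T) + a,      b = −Ea/R,  a = ln A
```

fitted by ordinary least squares, with multi-study data pooled by plain
concatenation. Inference uses the classical confidence band for the mean
response,

```
ln k̂(T) ± t(p, n−2) · s · sqrt( 1/n + (1/T − m)² / Sxx )
```

with s² = RSS/(n−2), m the mean of the 1/T values and Sxx their sum of
squared deviations; *p* is the two-tailed tail mass (the Excel `TINV`
convention). Inverting the band against a target rate k\* = ln 2 / t½\*
gives the stability confidence

```
C(T) = F_t[ (ln k* − ln k̂(T)) / SE(T); n−2 ]
```

swept over 300–640 K. A metabolite is *stable* when C(420 K) ≥ 0.95 for
its class's long target half-life; otherwise the curve's shape separates
genuine *lability* (a steep, decisive curve) from *uncertainty* (a shallow
curve, the signature of discordant studies). Class target half-lives
(amino acids, sugars, nucleotides, …) ship as a built-in registry and can
be overridden.

## Worked example

Generate a two-study synthetic dataset from a known Arrhenius law
(Ea = 120 kJ/mol, ln A = 28, σ_lnk = 0.05) and run the pipeline:

```python
from thermokin import SyntheticSpec, generate_studies, run_pipeline
from thermokin.io import measurements_to_frame

spec = SyntheticSpec(
    metabolite_id="fructose_like", true_Ea=120e3, true_lnA=28.0,
    temps_per_study=((410., 430., 450., 470.), (420., 440., 460., 480.)),
    residual_sd=0.05, seed=4)
points, truth = generate_studies(spec)
measurements_to_frame(points, {"fructose_like": "S"}).to_csv("rates.csv", index=False)
result = run_pipeline("rates.csv", out_dir="out")

fit = result.fits["fructose_like"]
a = result.assessments[0]
print(f"Ea = {fit.activation_energy/1e3:.1f} kJ/mol, n = {fit.n_points}")
print(f"t50(600 s) = {a.t50_long:.1f} K, t50(60 s) = {a.t50_short:.1f} K, call = {a.call}")
```

prints

```
Ea = 118.4 kJ/mol, n = 8
t50(600 s) = 414.9 K, t50(60 s) = 444.6 K, call = labile
```

The pooled fit recovers the true activation energy to ~1%. The 0.5-crossing
temperatures say: we are 50% confident the mean decomposition rate respects
a 600 s half-life up to ~415 K (142 °C) and a 60 s half-life up to ~445 K
(171 °C). The metabolite is called *labile* because its confidence at the
420 K reference is below 0.95 for the long target while the curve itself is
steep — the data are decisive, the molecule is just not stable enough
there. `out/` receives `fits.csv`, `curves.csv`, `assessments.csv`,
`histogram.csv` and `exclusions.log`.

The same pipeline is scriptable from a shell:

```
thermokin report rates.csv -o out --plots
thermokin pressure --delta-p 217 --delta-v 20
thermokin q10 out/fits.csv -T 310
```

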