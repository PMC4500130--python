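"""Synthetic multi-study kinetic data with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
metabolite obeys a single Arrhenius law, every study contributes >= 3
(T, k) points, and measurement variability is Gaussian in ln k. A per-study
intercept offset (study bias) reproduces the systematic inter-laboratory
discrepancies that make pooled confidence curves shallow:

    ln k_ij = true_lnA - true_Ea / (R * T_ij) + beta_i + eps_ij
    beta_i ~ N(0, study_bias_sd^2),   eps_ij ~ N(0, residual_sd^2)

All randomness flows from an explicit integer seed through one
numpy Generator per call — no hidden global state — so every dataset,
fixture and simulation is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arrhenius import GAS_CONSTANT, confidence_band, fit_arrhenius, predict_lnk
from .kinetics import RateMeasurement, TimeCourse

__all__ = [
    "SyntheticSpec",
    "TruthManifest",
    "generate_studies",
    "generate_timecourse",
    "xylose_like_scenario",
    "XyloseLikeScenario",
    "CoverageResult",
    "monte_carlo_band_coverage",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for a synthetic multi-study dataset.

    true_Ea in J/mol (> 0), true_lnA dimensionless; temps_per_study is one
    kelvin collection per study, each with >= 3 distinct values so every
    generated study passes the literature inclusion rule by construction;
    residual_sd and study_bias_sd are ln-k-scale standard deviations.
    """

    metabolite_id: str
    true_Ea: float
    true_lnA: float
    temps_per_study: tuple[tuple[float, ...], ...]
    residual_sd: float = 0.0
    study_bias_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_Ea <= 0:
            raise ValueError("true_Ea must be > 0 J/mol")
        if self.residual_sd < 0 or self.study_bias_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        temps = tuple(tuple(float(t) for t in ts) for ts in self.temps_per_study)
        if len(temps) < 1:
            raise ValueError("need at least one study")
        for ts in temps:
            if len(set(ts)) < 3:
                raise ValueError("every study needs >= 3 distinct temperatures")
        object.__setattr__(self, "temps_per_study", temps)

    @property
    def n_studies(self) -> int:
        return len(self.temps_per_study)

    def true_lnk(self, temperature) -> np.ndarray | float:
        t = np.asarray(temperature, dtype=float)
        lnk = self.true_lnA - self.true_Ea / (GAS_CONSTANT * t)
        return float(lnk) if t.ndim == 0 else lnk


@dataclass(frozen=True)
class TruthManifest:
    """Record of the parameters and realized study biases behind a dataset."""

    metabolite_id: str
    true_Ea: float
    true_lnA: float
    residual_sd: float
    study_bias_sd: float
    seed: int
    study_biases: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per study; shortest-repr floats round-trip through CSV."""
        return pd.DataFrame(
            {
                "metabolite_id": self.metabolite_id,
                "study_id": list(self.study_biases),
                "study_bias": list(self.study_biases.values()),
                "true_Ea": self.true_Ea,
                "true_lnA": self.true_lnA,
                "residual_sd": self.residual_sd,
                "study_bias_sd": self.study_bias_sd,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthManifest":
        first = df.iloc[0]
        return cls(
            metabolite_id=str(first["metabolite_id"]),
            true_Ea=float(first["true_Ea"]),
            true_lnA=float(first["true_lnA"]),
            residual_sd=float(first["residual_sd"]),
            study_bias_sd=float(first["study_bias_sd"]),
            seed=int(first["seed"]),
            study_biases={
                str(r["study_id"]): float(r["study_bias"]) for _, r in df.iterrows()
            },
        )


def generate_studies(
    spec: SyntheticSpec,
) -> tuple[list[RateMeasurement], TruthManifest]:
    """Draw a multi-study dataset from the spec's Arrhenius ground truth.

    Deterministic for a fixed spec (including its seed). Returns the flat
    list of measurements (study_id "S1", "S2", ...) and the truth manifest
    recording the realized per-study biases.
    """
    rng = np.random.default_rng(spec.seed)
    biases = rng.normal(0.0, spec.study_bias_sd, size=spec.n_studies)
    measurements: list[RateMeasurement] = []
    bias_map: dict[str, float] = {}
    for i, temps in enumerate(spec.temps_per_study):
        study_id = f"S{i + 1}"
        bias_map[study_id] = float(biases[i])
        for t in temps:
            lnk = (
                spec.true_lnk(t)
                + biases[i]
                + rng.normal(0.0, spec.residual_sd)
            )
            measurements.append(
                RateMeasurement(
                    metabolite_id=spec.metabolite_id,
                    study_id=study_id,
                    temperature=t,
                    rate_k=float(np.exp(lnk)),
                )
            )
    manifest = TruthManifest(
        metabolite_id=spec.metabolite_id,
        true_Ea=spec.true_Ea,
        true_lnA=spec.true_lnA,
        residual_sd=spec.residual_sd,
        study_bias_sd=spec.study_bias_sd,
        seed=spec.seed,
        study_biases=bias_map,
    )
    return measurements, manifest


def generate_timecourse(
    k: float,
    c0: float,
    times: Sequence[float],
    noise_sd: float,
    seed: int,
    metabolite_id: str = "synthetic",
    study_id: str = "sim",
    temperature: float = 298.15,
) -> TimeCourse:
    """Exponential-decay time course with multiplicative ln-scale noise.

    concentrations = c0 * exp(-k t) * exp(N(0, noise_sd^2)) per point; noise
    in log space keeps concentrations positive, matching the space in which
    the rate is subsequently fitted. k = 0 yields a flat (noisy) series.
    """
    if k < 0 or c0 <= 0 or noise_sd < 0:
        raise ValueError("need k >= 0, c0 > 0, noise_sd >= 0")
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    rng = np.random.default_rng(seed)
    conc = c0 * np.exp(-k * t) * np.exp(rng.normal(0.0, noise_sd, size=t.size))
    return TimeCourse(
        metabolite_id=metabolite_id,
        study_id=study_id,
        temperature=temperature,
        times=t,
        concentrations=conc,
    )


@dataclass(frozen=True)
class XyloseLikeScenario:
    """Three-study fixture with one systematically discrepant study.

    Two studies share the true Arrhenius line; the third carries a large
    negative intercept offset and sits at higher temperatures, so pooling
    all three flattens the fitted slope and inflates the residual scatter —
    the shallow-confidence-curve regime — while pooling only the consistent
    pair keeps the curve steep.
    """

    studies: tuple[tuple[RateMeasurement, ...], ...]
    consistent_ids: tuple[str, str]
    biased_id: str
    manifest: TruthManifest

    @property
    def all_measurements(self) -> list[RateMeasurement]:
        return [m for study in self.studies for m in study]

    @property
    def consistent_measurements(self) -> list[RateMeasurement]:
        return [
            m
            for study in self.studies
            for m in study
            if m.study_id in self.consistent_ids
        ]


def xylose_like_scenario(seed: int = 0) -> XyloseLikeScenario:
    """Construct the discrepant-study fixture.

    Ground truth: Ea = 120 kJ/mol, lnA = 28 (a 60 s half-life near 445 K).
    Studies S1 (3 temps) and S2 (3 temps) sample the true line with small
    residual noise; S3 (4 temps, higher range) is offset by -4 in ln k,
    mimicking a lab that tracked a slow minor product. The offset is a fixed
    feature of the fixture, not a random draw.
    """
    true_Ea, true_lnA = 120e3, 28.0
    bias_s3 = -4.0
    residual_sd = 0.08
    rng = np.random.default_rng(seed)
    layout = {
        "S1": ([415.0, 440.0, 465.0], 0.0),
        "S2": ([425.0, 450.0, 475.0], 0.0),
        "S3": ([480.0, 500.0, 520.0, 540.0], bias_s3),
    }
    studies = []
    for study_id, (temps, bias) in layout.items():
        pts = []
        for t in temps:
            lnk = (
                true_lnA
                - true_Ea / (GAS_CONSTANT * t)
                + bias
                + rng.normal(0.0, residual_sd)
            )
            pts.append(
                RateMeasurement(
                    metabolite_id="xylose_like",
                    study_id=study_id,
                    temperature=t,
                    rate_k=float(np.exp(lnk)),
                )
            )
        studies.append(tuple(pts))
    manifest = TruthManifest(
        metabolite_id="xylose_like",
        true_Ea=true_Ea,
        true_lnA=true_lnA,
        residual_sd=residual_sd,
        study_bias_sd=0.0,
        seed=seed,
        study_biases={"S1": 0.0, "S2": 0.0, "S3": bias_s3},
    )
    return XyloseLikeScenario(
        studies=tuple(studies),
        consistent_ids=("S1", "S2"),
        biased_id="S3",
        manifest=manifest,
    )


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of a Monte-Carlo band-coverage simulation."""

    coverage: float
    ea_mean: float
    ea_sd: float
    n_replicates: int

    @property
    def ea_standard_error(self) -> float:
        """Monte-Carlo standard error of the mean fitted Ea."""
        return self.ea_sd / np.sqrt(self.n_replicates)


def monte_carlo_band_coverage(
    spec: SyntheticSpec,
    n_replicates: int,
    p: float,
    test_temperature: float,
    seed: int,
) -> CoverageResult:
    """Empirical coverage of the mean-response band, plus Ea recovery.

    Regenerates the spec's dataset `n_replicates` times (replicate seeds
    spawned deterministically from `seed`), fits each, and checks whether
    the two-tailed-p confidence band at `test_temperature` contains the
    true mean ln k there. With no study bias the coverage of a nominal 95%
    band should land near 0.95, and the fitted Ea should be unbiased.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    true_lnk = spec.true_lnk(test_temperature)
    hits = 0
    eas = np.empty(n_replicates)
    for i, s in enumerate(child_seeds):
        rep_spec = dataclasses.replace(spec, seed=int(s))
        points, _ = generate_studies(rep_spec)
        fit = fit_arrhenius(points)
        lower, upper = confidence_band(fit, test_temperature, p)
        if lower <= true_lnk <= upper:
            hits += 1
        eas[i] = fit.activation_energy
    return CoverageResult(
        coverage=hits / n_replicates,
        ea_mean=float(eas.mean()),
        ea_sd=float(eas.std(ddof=1)),
        n_replicates=n_replicates,
    )
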