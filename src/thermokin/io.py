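"""File formats, configuration and the end-to-end pipeline.

Everything on disk is plain UTF-8 CSV (dot decimal separator, RFC 4180) or
YAML. Temperatures are kelvin internally and in all input files unless the
``celsius_input`` flag is set, in which case the I/O boundary converts;
report tables print both K and degrees C.

The rates table has columns ``metabolite, class_code, study_id,
temperature`` and exactly one of ``k_per_s`` / ``half_life_s`` filled per
row (half-lives are converted to rates on ingest). Rows that violate type
invariants are rejected individually with line-numbered diagnostics;
structural problems (missing columns, a row carrying both a rate and a
half-life, an empty file) abort with a format error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .arrhenius import ArrheniusFit, fit_arrhenius, pool_studies
from .kinetics import RateMeasurement, TimeCourse, rate_from_halflife
from .stability import (
    DEFAULT_TARGETS,
    ConfidenceCurve,
    HalfLifeTarget,
    StabilityAssessment,
    StabilityClassifier,
    histogram_t50,
    stability_curve,
)

__all__ = [
    "FormatError",
    "PipelineError",
    "PipelineConfig",
    "RatesTable",
    "read_rates_table",
    "read_timecourse_table",
    "read_targets_table",
    "write_targets_table",
    "measurements_to_frame",
    "fits_to_frame",
    "curves_to_frame",
    "assessments_to_frame",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("thermokin")

KELVIN_OFFSET = 273.15


class FormatError(ValueError):
    """An input file is structurally unusable (not a per-row data problem)."""


class PipelineError(RuntimeError):
    """The pipeline cannot produce any result (e.g. nothing passes inclusion)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the analysis.

    Defaults encode the published procedure: a 300-640 K window walked in
    1 K steps, classification at 420 K against 95% confidence, a 100 K
    steepness span for the labile/uncertain split, and the built-in
    class-target registry.
    """

    temperature_window: tuple[float, float] = (300.0, 640.0)
    grid_step: float = 1.0
    p_grid_step: float = 0.005
    ref_temperature: float = 420.0
    conf_threshold: float = 0.95
    steepness_span: float = 100.0
    targets: Mapping[str, HalfLifeTarget] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    celsius_input: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.temperature_window
        if not (250.0 <= lo < hi <= 700.0):
            raise ValueError("temperature_window must be ordered within [250, 700] K")
        if not 0 < self.conf_threshold < 1:
            raise ValueError("conf_threshold must lie in (0, 1)")
        if not 0 < self.p_grid_step < 1:
            raise ValueError("p_grid_step must lie in (0, 1)")
        if self.grid_step <= 0 or self.steepness_span <= 0:
            raise ValueError("grid_step and steepness_span must be > 0")

    def temperature_grid(self) -> np.ndarray:
        lo, hi = self.temperature_window
        return np.arange(lo, hi + self.grid_step / 2, self.grid_step)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides beat file values."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "temperature_window" in raw:
            raw["temperature_window"] = tuple(raw["temperature_window"])
        if "targets" in raw:
            raw["targets"] = {
                code: HalfLifeTarget(code, float(v["long_halflife_s"]), float(v["short_halflife_s"]))
                for code, v in raw["targets"].items()
            }
        raw.update(overrides)
        return cls(**raw)


@dataclass(frozen=True)
class RowDiagnostic:
    line: int
    reason: str
    detail: str = ""


@dataclass
class RatesTable:
    """Parsed rates file: measurements grouped by metabolite and study."""

    by_metabolite: dict[str, dict[str, list[RateMeasurement]]]
    class_codes: dict[str, str]
    rejected: list[RowDiagnostic]
    n_accepted: int

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def measurements(self) -> list[RateMeasurement]:
        return [
            m
            for studies in self.by_metabolite.values()
            for pts in studies.values()
            for m in pts
        ]


_RATE_COLUMNS = ["metabolite", "class_code", "study_id", "temperature"]


def read_rates_table(path: str | Path, config: PipelineConfig | None = None) -> RatesTable:
    """Read a rates CSV into grouped, validated measurements.

    Half-life rows are converted to rate constants on the way in; Celsius
    temperatures are converted when the config sets ``celsius_input``. Line
    numbers in diagnostics refer to the physical file (header = line 1).
    """
    config = config or PipelineConfig()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in _RATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    has_k = "k_per_s" in df.columns
    has_hl = "half_life_s" in df.columns
    if not (has_k or has_hl):
        raise FormatError(f"{path}: need a k_per_s or half_life_s column")
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    by_met: dict[str, dict[str, list[RateMeasurement]]] = {}
    class_codes: dict[str, str] = {}
    rejected: list[RowDiagnostic] = []
    n_ok = 0
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header occupies line 1
        k_val = row["k_per_s"] if has_k else np.nan
        hl_val = row["half_life_s"] if has_hl else np.nan
        if pd.notna(k_val) and pd.notna(hl_val):
            raise FormatError(
                f"{path}:{line}: row carries both k_per_s and half_life_s"
            )
        try:
            if pd.notna(k_val):
                k = float(k_val)
            elif pd.notna(hl_val):
                k = rate_from_halflife(float(hl_val))
            else:
                raise ValueError("row has neither k_per_s nor half_life_s")
            temp = float(row["temperature"])
            if config.celsius_input:
                temp += KELVIN_OFFSET
            m = RateMeasurement(
                metabolite_id=str(row["metabolite"]),
                study_id=str(row["study_id"]),
                temperature=temp,
                rate_k=k,
            )
        except (ValueError, TypeError) as exc:
            rejected.append(RowDiagnostic(line, "invalid_row", str(exc)))
            continue
        by_met.setdefault(m.metabolite_id, {}).setdefault(m.study_id, []).append(m)
        class_codes.setdefault(m.metabolite_id, str(row["class_code"]))
        n_ok += 1
    return RatesTable(by_met, class_codes, rejected, n_ok)


def read_timecourse_table(
    path: str | Path, config: PipelineConfig | None = None
) -> list[TimeCourse]:
    """Read a time-course CSV (metabolite, study_id, temperature, time_s,
    concentration), grouped into one TimeCourse per
    (metabolite, study, temperature)."""
    config = config or PipelineConfig()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["metabolite", "study_id", "temperature", "time_s", "concentration"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    courses = []
    for (met, study, temp), grp in df.groupby(
        ["metabolite", "study_id", "temperature"], sort=False
    ):
        grp = grp.sort_values("time_s")
        t = float(temp) + (KELVIN_OFFSET if config.celsius_input else 0.0)
        courses.append(
            TimeCourse(
                metabolite_id=str(met),
                study_id=str(study),
                temperature=t,
                times=grp["time_s"].to_numpy(dtype=float),
                concentrations=grp["concentration"].to_numpy(dtype=float),
            )
        )
    return courses


def read_targets_table(path: str | Path) -> dict[str, HalfLifeTarget]:
    """Read a class-target registry CSV
    (class_code, long_halflife_s, short_halflife_s)."""
    df = pd.read_csv(path)
    required = ["class_code", "long_halflife_s", "short_halflife_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return {
        str(r["class_code"]): HalfLifeTarget(
            str(r["class_code"]),
            float(r["long_halflife_s"]),
            float(r["short_halflife_s"]),
        )
        for _, r in df.iterrows()
    }


def write_targets_table(targets: Mapping[str, HalfLifeTarget], path: str | Path) -> None:
    pd.DataFrame(
        {
            "class_code": [t.class_code for t in targets.values()],
            "long_halflife_s": [t.long_halflife for t in targets.values()],
            "short_halflife_s": [t.short_halflife for t in targets.values()],
        }
    ).to_csv(path, index=False)


def measurements_to_frame(measurements: list[RateMeasurement],
                          class_codes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tidy frame in the rates-CSV dialect (kelvin, k_per_s)."""
    class_codes = class_codes or {}
    return pd.DataFrame(
        {
            "metabolite": [m.metabolite_id for m in measurements],
            "class_code": [class_codes.get(m.metabolite_id, "") for m in measurements],
            "study_id": [m.study_id for m in measurements],
            "temperature": [m.temperature for m in measurements],
            "k_per_s": [m.rate_k for m in measurements],
        }
    )


def fits_to_frame(fits: Mapping[str, ArrheniusFit]) -> pd.DataFrame:
    rows = []
    for met, f in fits.items():
        lo, hi = f.temperature_range
        rows.append(
            {
                "metabolite": met,
                "gradient_b_K": f.gradient_b,
                "intercept_a": f.intercept_a,
                "Ea_kJ_mol": f.activation_energy / 1e3,
                "n_points": f.n_points,
                "rss": f.rss,
                "mean_invT_perK": f.mean_inv_temp,
                "sxx_perK2": f.sxx,
                "T_min_K": lo,
                "T_max_K": hi,
                "T_min_C": lo - KELVIN_OFFSET,
                "T_max_C": hi - KELVIN_OFFSET,
            }
        )
    return pd.DataFrame(rows)


def curves_to_frame(curves: Mapping[str, Mapping[str, ConfidenceCurve]]) -> pd.DataFrame:
    frames = []
    for met, pair in curves.items():
        for kind, c in pair.items():
            frames.append(
                pd.DataFrame(
                    {
                        "metabolite": met,
                        "target": kind,
                        "target_halflife_s": c.target_halflife,
                        "temperature_K": c.temperatures,
                        "temperature_C": c.temperatures - KELVIN_OFFSET,
                        "confidence": c.confidences,
                        "extrapolated": c.extrapolated,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def assessments_to_frame(assessments: list[StabilityAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite": [a.metabolite_id for a in assessments],
            "class_code": [a.class_code for a in assessments],
            "t50_long_K": [a.t50_long for a in assessments],
            "t50_short_K": [a.t50_short for a in assessments],
            "t50_long_C": [
                None if a.t50_long is None else a.t50_long - KELVIN_OFFSET
                for a in assessments
            ],
            "t50_short_C": [
                None if a.t50_short is None else a.t50_short - KELVIN_OFFSET
                for a in assessments
            ],
            "conf_at_ref_long": [a.conf_at_ref_long for a in assessments],
            "conf_at_ref_short": [a.conf_at_ref_short for a in assessments],
            "call": [a.call for a in assessments],
            "short_vulnerable": [a.short_vulnerable for a in assessments],
            "t50_long_reason": [a.t50_long_reason for a in assessments],
            "t50_short_reason": [a.t50_short_reason for a in assessments],
        }
    )


@dataclass(frozen=True)
class Exclusion:
    """One excluded datum with a machine-readable reason code."""

    metabolite_id: str
    study_id: str | None
    reason: str
    detail: str = ""

    def as_line(self) -> str:
        scope = self.metabolite_id if self.study_id is None else f"{self.metabolite_id}/{self.study_id}"
        return f"{scope}\t{self.reason}\t{self.detail}"


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, in memory."""

    fits: dict[str, ArrheniusFit]
    curves: dict[str, dict[str, ConfidenceCurve]]
    assessments: list[StabilityAssessment]
    histogram: pd.DataFrame
    histogram_absent: dict[str, int]
    exclusions: list[Exclusion]
    rejected_rows: list[RowDiagnostic]
    config: PipelineConfig


def run_pipeline(
    rates_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> PipelineResult:
    """End-to-end analysis of a rates CSV.

    Per metabolite: studies with fewer than three distinct temperatures are
    excluded (the literature inclusion rule, logged with a reason code);
    remaining studies are pooled into one OLS Arrhenius fit; long- and
    short-target stability curves are computed on the configured grid and
    classified. Output is a pure function of the input bytes and the
    config — no randomness anywhere in the pipeline.

    When `out_dir` is given, writes fits.csv, curves.csv, assessments.csv,
    histogram.csv and exclusions.log there (plus PNG plots if requested).
    """
    config = config or PipelineConfig()
    table = read_rates_table(rates_path, config)
    grid = config.temperature_grid()
    classifier = StabilityClassifier(
        ref_temperature=config.ref_temperature,
        conf_threshold=config.conf_threshold,
        steepness_span=config.steepness_span,
    )

    fits: dict[str, ArrheniusFit] = {}
    curves: dict[str, dict[str, ConfidenceCurve]] = {}
    assessments: list[StabilityAssessment] = []
    exclusions: list[Exclusion] = []
    for diag in table.rejected:
        exclusions.append(
            Exclusion("<row>", None, "invalid_row", f"line {diag.line}: {diag.detail}")
        )

    for met, studies in table.by_metabolite.items():
        kept = {}
        for study_id, pts in studies.items():
            if len({p.temperature for p in pts}) < 3:
                exclusions.append(
                    Exclusion(
                        met,
                        study_id,
                        "study_too_few_temperatures",
                        "needs >= 3 distinct temperatures",
                    )
                )
            else:
                kept[study_id] = pts
        if not kept:
            exclusions.append(
                Exclusion(met, None, "metabolite_no_qualifying_study")
            )
            continue
        code = table.class_codes.get(met, "")
        target = config.targets.get(code)
        if target is None:
            exclusions.append(
                Exclusion(met, None, "unknown_class_code", f"class_code={code!r}")
            )
            continue

        fit = fit_arrhenius(pool_studies(kept.values()))
        fits[met] = fit
        pair = {
            "long": stability_curve(
                fit, target.long_halflife, grid, metabolite_id=met,
                window=config.temperature_window,
            ),
            "short": stability_curve(
                fit, target.short_halflife, grid, metabolite_id=met,
                window=config.temperature_window,
            ),
        }
        curves[met] = pair
        assessments.append(classifier.assess(pair["long"], pair["short"], class_code=code))
        if fit.is_extrapolation(grid).any():
            log.info(
                "%s: stability curve extrapolates beyond fitted range %s",
                met,
                fit.temperature_range,
            )

    if not fits:
        raise PipelineError("no metabolite passed the inclusion rule; nothing to analyse")

    hist, absent = histogram_t50(assessments, bin_width=10.0)
    result = PipelineResult(
        fits, curves, assessments, hist, absent, exclusions, table.rejected, config
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), plots=plots)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, plots: bool = False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fits_to_frame(result.fits).to_csv(out_dir / "fits.csv", index=False)
    curves_to_frame(result.curves).to_csv(out_dir / "curves.csv", index=False)
    assessments_to_frame(result.assessments).to_csv(
        out_dir / "assessments.csv", index=False
    )
    hist = result.histogram.copy()
    hist.to_csv(out_dir / "histogram.csv", index=False)
    with open(out_dir / "exclusions.log", "w", encoding="utf-8") as fh:
        for e in result.exclusions:
            fh.write(e.as_line() + "\n")
    if plots:
        from .plotting import plot_confidence_curves, plot_histogram

        plot_confidence_curves(result.curves, out_dir / "curves.png")
        plot_histogram(result.histogram, out_dir / "histogram.png")
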