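"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's fitting code paths: OLS
slopes/intercepts and confidence half-widths are computed from explicit
summation formulas so that regressions in the library cannot hide in the
expectations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from thermokin.arrhenius import GAS_CONSTANT, ArrheniusFit
from thermokin.kinetics import RateMeasurement


def ols_summation_oracle(x: np.ndarray, y: np.ndarray):
    """Textbook OLS via raw sums: slope, intercept, rss, mean_x, sxx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx_raw = (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx_raw - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    return {
        "slope": slope,
        "intercept": intercept,
        "rss": float(resid @ resid),
        "mean_x": sx / n,
        "sxx": float(((x - sx / n) ** 2).sum()),
    }


def band_halfwidth_oracle(stats_dict: dict, n: int, x0: float, p: float) -> float:
    """Mean-response half-width from the summation-oracle statistics."""
    from scipy import stats as st

    s = math.sqrt(stats_dict["rss"] / (n - 2))
    lever = 1.0 / n + (x0 - stats_dict["mean_x"]) ** 2 / stats_dict["sxx"]
    return float(st.t.ppf(1 - p / 2, n - 2)) * s * math.sqrt(lever)


def measurements_from_lnk(
    temps, lnk, metabolite="met", study="S1"
) -> list[RateMeasurement]:
    return [
        RateMeasurement(metabolite, study, float(t), float(np.exp(v)))
        for t, v in zip(temps, lnk)
    ]


def arrhenius_lnk(temps, ea, lna):
    t = np.asarray(temps, dtype=float)
    return lna - ea / (GAS_CONSTANT * t)


@pytest.fixture
def exact_fit() -> ArrheniusFit:
    """Degenerate rss = 0 fit: Ea = 120 kJ/mol, lnA = 30, three temps.

    Built directly (not via the fitter) so rss is exactly zero and the
    degenerate-band conventions can be asserted as hard steps.
    """
    x = 1.0 / np.array([400.0, 450.0, 500.0])
    m = float(x.mean())
    return ArrheniusFit(
        gradient_b=-120e3 / GAS_CONSTANT,
        intercept_a=30.0,
        n_points=3,
        rss=0.0,
        mean_inv_temp=m,
        sxx=float(((x - m) ** 2).sum()),
        temperature_range=(400.0, 500.0),
    )


@pytest.fixture
def noisy_fit() -> ArrheniusFit:
    """A realistic fit: 12 points, sigma_lnk = 0.3, fixed seed."""
    from thermokin.arrhenius import fit_arrhenius

    rng = np.random.default_rng(42)
    temps = np.linspace(380.0, 520.0, 12)
    lnk = arrhenius_lnk(temps, 110e3, 27.0) + rng.normal(0, 0.3, temps.size)
    return fit_arrhenius(measurements_from_lnk(temps, lnk))


def random_fits(n_fits: int, seed: int) -> list[ArrheniusFit]:
    """Diverse random-but-reproducible Arrhenius fits for sweeps."""
    from thermokin.arrhenius import fit_arrhenius

    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_fits):
        n = int(rng.integers(4, 15))
        lo = rng.uniform(330.0, 450.0)
        temps = np.linspace(lo, lo + rng.uniform(40.0, 150.0), n)
        ea = rng.uniform(60e3, 160e3)
        lna = rng.uniform(15.0, 35.0)
        sigma = rng.uniform(0.05, 0.6)
        lnk = arrhenius_lnk(temps, ea, lna) + rng.normal(0, sigma, n)
        fits.append(fit_arrhenius(measurements_from_lnk(temps, lnk)))
    return fits
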