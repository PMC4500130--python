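"""First-order rate-law primitives.

Decomposition of a dilute solute M in water is treated as pseudo-first-order
(water is in vast excess, so its concentration is absorbed into the rate
constant):

    -d[M]/dt = k [M]        =>      [M](t) = [M]0 exp(-k t)

which ties the rate constant to the half-life via k = ln(2) / t_half.
This module provides the half-life <-> rate conversions and extraction of k
from a concentration time course by log-linear ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LN2",
    "RateMeasurement",
    "TimeCourse",
    "rate_from_halflife",
    "halflife_from_rate",
    "FirstOrderDecay",
    "fit_first_order",
]

LN2 = math.log(2.0)

#: Plausibility window for absolute temperatures (K); anything outside is
#: almost certainly a unit error (Celsius passed as Kelvin, or vice versa).
TEMPERATURE_SANITY_K = (250.0, 700.0)


@dataclass(frozen=True)
class RateMeasurement:
    """One (temperature, rate constant) observation from a single study.

    Parameters
    ----------
    metabolite_id : str
        Identifier of the compound the rate refers to.
    study_id : str
        Identifier of the source study (provenance is preserved through
        pooling).
    temperature : float
        Absolute temperature in kelvin; must lie in the (250, 700) K sanity
        window.
    rate_k : float
        First-order rate constant in s^-1; strictly positive so that ln(k)
        exists.
    """

    metabolite_id: str
    study_id: str
    temperature: float
    rate_k: float

    def __post_init__(self) -> None:
        lo, hi = TEMPERATURE_SANITY_K
        if not (lo < self.temperature < hi):
            raise ValueError(
                f"temperature {self.temperature!r} K outside sanity window "
                f"({lo}, {hi}) K"
            )
        if not (math.isfinite(self.rate_k) and self.rate_k > 0):
            raise ValueError(f"rate_k must be finite and > 0, got {self.rate_k!r}")

    @property
    def ln_k(self) -> float:
        return math.log(self.rate_k)

    @property
    def inv_temperature(self) -> float:
        return 1.0 / self.temperature


@dataclass(frozen=True)
class TimeCourse:
    """Concentration-vs-time series at a fixed temperature.

    Requires at least three points (so a fitted slope retains residual
    degrees of freedom), strictly increasing times and strictly positive
    concentrations (the log must exist; zero/negative readings are rejected
    rather than silently dropped, since truncation would bias k).
    """

    metabolite_id: str
    study_id: str
    temperature: float
    times: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D of equal length")
        if t.size < 3:
            raise ValueError("a time course needs >= 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("all concentrations must be finite and > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def rate_from_halflife(t_half: float) -> float:
    """First-order rate constant (s^-1) for a given half-life (s).

    k = ln(2) / t_half. For example a 60 s half-life corresponds to
    k = 0.01155 s^-1, i.e. ln(k) = -4.46.
    """
    if not (math.isfinite(t_half) and t_half > 0):
        raise ValueError(f"t_half must be finite and > 0, got {t_half!r}")
    return LN2 / t_half


def halflife_from_rate(k: float) -> float:
    """Half-life (s) for a first-order rate constant (s^-1); t_half = ln(2)/k."""
    if not (math.isfinite(k) and k > 0):
        raise ValueError(f"k must be finite and > 0, got {k!r}")
    return LN2 / k


class FirstOrderDecay(RegressorMixin, BaseEstimator):
    """First-order decay fitted by ordinary least squares on ln(concentration).

    ``fit(X, y)`` takes times (s) as a single feature column and
    concentrations as the target; the model is
    ``ln C = ln C0 - k t`` fitted by OLS, which is deterministic and matches
    the first-order assumption exactly on noiseless exponentials.

    Attributes
    ----------
    rate_ : float
        The decay constant k (s^-1), the negated OLS slope. May be <= 0 for
        non-decaying input; this is reported, not raised.
    rate_stderr_ : float
        Standard error of the slope (0.0 when the fit is exact or has no
        residual degrees of freedom spare beyond the minimum).
    log_c0_ : float
        Fitted intercept, ln of the concentration at t = 0.
    n_points_ : int
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        c = np.asarray(y, dtype=float).reshape(-1)
        if t.size != c.size:
            raise ValueError("X and y must have the same number of samples")
        if t.size < 3:
            raise ValueError("need >= 3 points to fit a first-order decay")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("all concentrations must be finite and > 0")
        lnc = np.log(c)
        n = t.size
        tbar = t.mean()
        sxx = float(np.sum((t - tbar) ** 2))
        if sxx == 0.0:
            raise ValueError("times are all identical; slope is undefined")
        slope = float(np.sum((t - tbar) * (lnc - lnc.mean())) / sxx)
        intercept = float(lnc.mean() - slope * tbar)
        resid = lnc - (intercept + slope * t)
        rss = float(resid @ resid)
        # slope s.e. from residual variance; df = n - 2 is positive by the
        # >=3-point requirement
        sigma2 = rss / (n - 2)
        self.rate_ = -slope
        self.rate_stderr_ = math.sqrt(sigma2 / sxx)
        self.log_c0_ = intercept
        self.n_points_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "rate_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.log_c0_ - self.rate_ * t)


def fit_first_order(tc: TimeCourse) -> tuple[float, float]:
    """Extract (rate_k, stderr) from a time course by log-linear OLS.

    The returned rate is the negated slope of ln C on t. A non-decaying
    series yields rate_k <= 0 — flagged by sign, not an error, so callers
    can decide how to treat it.
    """
    est = FirstOrderDecay().fit(tc.times, tc.concentrations)
    return est.rate_, est.rate_stderr_
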