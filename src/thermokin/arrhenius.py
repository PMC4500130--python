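"""Arrhenius regression of ln(k) on 1/T with mean-response confidence bands.

The Arrhenius law k = A exp(-Ea/(R T)) is linear in transformed coordinates:

    ln k = b * (1/T) + a,   with b = -Ea/R and a = ln A.

Fitting is ordinary least squares (equal weights; pooled multi-study data
enter as plain concatenation). Inference on the fitted line uses the
classical confidence band for the *mean response*,

    ln k_hat(T) +/- t(p, n-2) * s * sqrt(1/n + (1/T - m)^2 / Sxx)

where s^2 = RSS/(n-2), m is the mean of the 1/T values, Sxx the sum of
squared deviations of 1/T, and t(p, df) the two-tailed Student-t critical
value (the Excel TINV convention: p is the total tail mass, so the band
covers the central 1-p probability). The band quantifies confidence in the
mean rate a large number of replicate experiments would find, which is the
quantity the downstream stability analysis needs — not the spread of single
new observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinetics import RateMeasurement

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusFit",
    "ArrheniusRegressor",
    "fit_arrhenius",
    "pool_studies",
    "predict_lnk",
    "confidence_band",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS fit of ln k on 1/T with the sufficient statistics for its band.

    Attributes
    ----------
    gradient_b : float
        Slope of ln k on 1/T, in kelvin; negative for thermally activated
        reactions (b = -Ea/R).
    intercept_a : float
        Intercept, ln of the pre-exponential factor A.
    n_points : int
    rss : float
        Residual sum of squares in ln k.
    mean_inv_temp : float
        Mean of the 1/T values (K^-1), the centroid where the band is
        narrowest.
    sxx : float
        Sum of squared deviations of 1/T about its mean (K^-2).
    temperature_range : tuple[float, float]
        (min, max) kelvin of the fitted data; predictions outside it are
        extrapolations.
    """

    gradient_b: float
    intercept_a: float
    n_points: int
    rss: float
    mean_inv_temp: float
    sxx: float
    temperature_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("an Arrhenius fit needs >= 3 points")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.sxx <= 0:
            raise ValueError("sxx must be > 0 (>= 2 distinct temperatures)")

    @property
    def activation_energy(self) -> float:
        """Activation energy Ea = -b * R, in J/mol."""
        return -self.gradient_b * GAS_CONSTANT

    @property
    def ln_A(self) -> float:
        return self.intercept_a

    @property
    def df(self) -> int:
        """Residual degrees of freedom, n - 2."""
        return self.n_points - 2

    @property
    def residual_sd(self) -> float:
        """s = sqrt(RSS / (n-2)), the residual standard deviation in ln k."""
        return math.sqrt(self.rss / self.df)

    def is_extrapolation(self, temperature) -> np.ndarray | bool:
        """Whether prediction at `temperature` lies outside the fitted range."""
        t = np.asarray(temperature, dtype=float)
        lo, hi = self.temperature_range
        out = (t < lo) | (t > hi)
        return bool(out) if out.ndim == 0 else out


class ArrheniusRegressor(RegressorMixin, BaseEstimator):
    """Arrhenius fit as an sklearn regressor: temperatures in, ln k out.

    ``fit(X, y)`` takes absolute temperatures (K) as a single feature column
    and ln k as the target; internally the regression is OLS of ln k on 1/T.
    ``predict(X)`` returns ln k at the requested temperatures (extrapolation
    beyond the fitted range is permitted; use :meth:`is_extrapolation` or
    ``result_.is_extrapolation`` to flag it).

    Requires >= 3 points at >= 3 distinct temperatures — the minimum for a
    slope, an intercept and a nonzero residual degree of freedom, and the
    inclusion rule applied to literature studies.

    Attributes
    ----------
    slope_, intercept_ : float
        b (K) and a of ln k = b/T + a.
    activation_energy_ : float
        Ea = -b R, J/mol.
    result_ : ArrheniusFit
        The immutable fit record consumed by the stability layer.
    """

    def fit(self, X, y):
        temps = np.asarray(X, dtype=float).reshape(-1)
        lnk = np.asarray(y, dtype=float).reshape(-1)
        if temps.size != lnk.size:
            raise ValueError("X and y must have the same number of samples")
        if temps.size < 3:
            raise ValueError("insufficient data: need >= 3 points")
        if np.unique(temps).size < 3:
            raise ValueError("insufficient data: need >= 3 distinct temperatures")
        if np.any(temps <= 0) or not np.all(np.isfinite(temps)):
            raise ValueError("temperatures must be finite and > 0 K")
        if not np.all(np.isfinite(lnk)):
            raise ValueError("ln k values must be finite")

        x = 1.0 / temps
        n = x.size
        m = float(x.mean())
        dx = x - m
        sxx = float(dx @ dx)
        b = float((dx @ (lnk - lnk.mean())) / sxx)
        a = float(lnk.mean() - b * m)
        resid = lnk - (a + b * x)
        rss = float(resid @ resid)

        self.slope_ = b
        self.intercept_ = a
        self.activation_energy_ = -b * GAS_CONSTANT
        self.n_points_ = n
        self.result_ = ArrheniusFit(
            gradient_b=b,
            intercept_a=a,
            n_points=n,
            rss=rss,
            mean_inv_temp=m,
            sxx=sxx,
            temperature_range=(float(temps.min()), float(temps.max())),
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        temps = np.asarray(X, dtype=float).reshape(-1)
        if np.any(temps <= 0):
            raise ValueError("temperatures must be > 0 K")
        return self.slope_ / temps + self.intercept_

    def is_extrapolation(self, X):
        check_is_fitted(self, "result_")
        return self.result_.is_extrapolation(np.asarray(X, dtype=float).reshape(-1))

    def confidence_band(self, X, p: float):
        """(lower, upper) mean-response band at two-tailed probability p."""
        check_is_fitted(self, "result_")
        return confidence_band(self.result_, np.asarray(X, dtype=float).reshape(-1), p)


def fit_arrhenius(points: Iterable[RateMeasurement]) -> ArrheniusFit:
    """Fit ln k = b/T + a by OLS over a collection of rate measurements.

    Raises ValueError with an insufficient-data message for < 3 points or
    < 3 distinct temperatures (the literature inclusion rule), mixed
    metabolites, or non-positive rates (screened at RateMeasurement
    construction).
    """
    pts = list(points)
    ids = {p.metabolite_id for p in pts}
    if len(ids) > 1:
        raise ValueError(f"measurements mix metabolites: {sorted(ids)}")
    temps = np.array([p.temperature for p in pts], dtype=float)
    lnk = np.array([p.ln_k for p in pts], dtype=float)
    return ArrheniusRegressor().fit(temps, lnk).result_


def pool_studies(
    datasets: Iterable[Sequence[RateMeasurement]],
) -> list[RateMeasurement]:
    """Concatenate per-study datasets for one metabolite into a single set.

    Pooling is plain concatenation with equal weights: no de-duplication and
    no reweighting — each published point counts once, and study_id
    provenance is preserved on every measurement.
    """
    pooled: list[RateMeasurement] = []
    for ds in datasets:
        pooled.extend(ds)
    ids = {p.metabolite_id for p in pooled}
    if len(ids) > 1:
        raise ValueError(f"cannot pool across metabolites: {sorted(ids)}")
    return pooled


def predict_lnk(fit: ArrheniusFit, temperature, *, return_flag: bool = False):
    """Predicted mean ln k at `temperature` (K): b/T + a.

    Extrapolation beyond the fitted temperature range is allowed; pass
    ``return_flag=True`` to also receive the per-point extrapolation flag.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    yhat = fit.gradient_b / t + fit.intercept_a
    if t.ndim == 0:
        yhat = float(yhat)
    if return_flag:
        return yhat, fit.is_extrapolation(temperature)
    return yhat


def standard_error_mean(fit: ArrheniusFit, temperature):
    """Standard error of the predicted mean ln k at `temperature`.

    s * sqrt(1/n + (1/T - m)^2 / Sxx); zero everywhere for an exact
    (rss = 0) fit.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    lever = 1.0 / fit.n_points + (1.0 / t - fit.mean_inv_temp) ** 2 / fit.sxx
    se = fit.residual_sd * np.sqrt(lever)
    return float(se) if t.ndim == 0 else se


def t_critical(p: float, df: int) -> float:
    """Two-tailed Student-t critical value (Excel TINV): P(|T| > t) = p."""
    if not 0 < p < 1:
        if p == 1.0:
            return 0.0
        raise ValueError("p must lie in (0, 1]")
    return float(stats.t.ppf(1.0 - p / 2.0, df))


def confidence_band(fit: ArrheniusFit, temperature, p: float):
    """(lower, upper) confidence limits on the mean ln k at `temperature`.

    Two-tailed probability `p` in (0, 1]: the band covers the central 1-p
    mass, so smaller p means a wider band. An exact fit (rss = 0) yields a
    degenerate zero-width band rather than an error.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    yhat = predict_lnk(fit, temperature)
    half = t_critical(p, fit.df) * standard_error_mean(fit, temperature)
    return yhat - half, yhat + half
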