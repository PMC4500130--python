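"""Pressure dependence of hydrolysis rates and Q10 temperature coefficients.

Pressure acts on a reaction through its activation volume dV (cm^3/mol),
the volume change between reactants and transition state. For hydrolysis of
uncharged species in water an empirical quadratic in x = dP * dV (atm
cm^3/mol) summarises the literature:

    ln(k_low / k_high) = -1.562e-11 x^2 - 4.18e-5 x

This module reports the reciprocal, k_high / k_low — the speed-up of the
reaction under the pressure increase — so positive dP*dV gives a factor
above 1 (solvolysis is faster under pressure). Note the quadratic term
breaks the naive antisymmetry: factor(dP, dV) * factor(dP, -dV) != 1.

Q10 — the factor a rate increases for a 10-degree temperature rise — falls
directly out of an Arrhenius fit: Q10(T) = exp(b * (1/(T+10) - 1/T)) with
b = -Ea/R, and decreases with temperature for any positive Ea.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .arrhenius import ArrheniusFit

__all__ = [
    "PRESSURE_COEF_QUADRATIC",
    "PRESSURE_COEF_LINEAR",
    "PressureScenario",
    "pressure_rate_factor",
    "q10",
    "mean_q10",
]

# Empirical coefficients of ln(k_l/k_h) in x = dP*dV (atm cm^3 mol^-1).
PRESSURE_COEF_QUADRATIC = -1.562e-11
PRESSURE_COEF_LINEAR = -4.18e-5


@dataclass(frozen=True)
class PressureScenario:
    """A pressure change applied to a reaction with a given activation volume.

    delta_p is the literal pressure difference (atm) from the caller's
    low-pressure reference (>= 0); activation_volume is signed, typically
    within +/- 20 cm^3/mol for organic reactions (|dV| > 100 is rejected as
    physically implausible).
    """

    delta_p: float
    activation_volume: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_p) and self.delta_p >= 0):
            raise ValueError("delta_p must be finite and >= 0 atm")
        if not math.isfinite(self.activation_volume) or abs(self.activation_volume) > 100:
            raise ValueError("|activation_volume| must be finite and <= 100 cm^3/mol")


def pressure_rate_factor(scenario: PressureScenario) -> float:
    """Rate ratio k_high / k_low for a pressure increase of delta_p.

    exp(1.562e-11 x^2 + 4.18e-5 x) with x = delta_p * activation_volume;
    values above 1 mean the reaction speeds up under pressure. At the
    critical pressure of water (dP = 217 atm from atmospheric) and
    |dV| = 20 cm^3/mol the change is at most ~20%.
    """
    x = scenario.delta_p * scenario.activation_volume
    return math.exp(-(PRESSURE_COEF_QUADRATIC * x * x + PRESSURE_COEF_LINEAR * x))


def q10(fit: ArrheniusFit, temperature: float) -> float:
    """Q10 = k(T+10)/k(T) implied by an Arrhenius fit at temperature T (K)."""
    if not (math.isfinite(temperature) and temperature > 0):
        raise ValueError("temperature must be finite and > 0 K")
    b = fit.gradient_b
    return math.exp(b * (1.0 / (temperature + 10.0) - 1.0 / temperature))


def mean_q10(fits: Iterable[ArrheniusFit], temperature: float) -> float:
    """Arithmetic mean of per-fit Q10 values at one temperature."""
    values = [q10(f, temperature) for f in fits]
    if not values:
        raise ValueError("need at least one fit")
    return sum(values) / len(values)
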