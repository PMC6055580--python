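"""Vital rates for one age class: growth, predator reaction distance,
functional responses, mortality and the growth/mortality fitness score.

Growth follows a Monod (saturating) response to food with additive linear
penalties for conspecific density (interference), log-light exposure (worse
for adults) and predator chemical cues.  Predation mortality is derived
from the visual predator's reaction distance: light and its spectral
composition set the reaction distance, a cylindrical search volume converts
it to an attack (clearance) rate, and a threshold disc equation (Holling
type II, or type III with a foraging-initiation threshold) converts local
prey density into per-capita risk.  Fitness is the Werner-Gilliam
growth-to-mortality ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "RDParams",
    "FunctionalResponseParams",
    "MortalityParams",
    "PerceptionParams",
    "growth_rate",
    "reaction_distance",
    "attack_rate",
    "consumption_rate",
    "per_capita_fish_mortality",
    "total_mortality",
    "fitness",
    "calibrate_predator_density",
]

ADULT = "adult"
JUVENILE = "juvenile"


class InvalidRateError(ValueError):
    """Raised when a rate argument is outside its physical domain."""


@dataclass(frozen=True)
class GrowthParams:
    """Growth-rate model coefficients (all rates per day).

    g0 intercept; a1/a2 Monod asymptote scale and half-saturation
    (mg C/L); b interference slope per (ind/L); c juvenile light-cost slope
    per log10 light unit; u extra adult light cost; kappa kairomone cost.
    """

    g0: float = 0.05
    a1: float = 0.35
    a2: float = 0.164
    b: float = 0.001
    c: float = 0.005
    u: float = 0.010
    kappa: float = 0.02

    def __post_init__(self) -> None:
        if self.a2 <= 0:
            raise InvalidRateError("a2 (half-saturation) must be > 0")
        if self.a1 < 0 or self.b < 0:
            raise InvalidRateError("a1 and b must be >= 0")


@dataclass(frozen=True)
class RDParams:
    """Reaction-distance model: r0 + k*log10(1+light) + l*[adult], scaled by
    the spectral factor w_red*alpha + w_green + w_blue*phi (cm)."""

    r0: float = 0.5
    k: float = 1.5
    l: float = 1.3
    alpha: float = 0.6
    phi: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise InvalidRateError("alpha must be in (0, 1]")

    def band_factor(self, weights) -> float:
        w = np.asarray(weights, dtype=float)
        return float(w[..., 0] * self.alpha + w[..., 1] + w[..., 2] * self.phi)


@dataclass(frozen=True)
class FunctionalResponseParams:
    """Threshold disc equation parameters.

    attack: liters cleared per predator per day; handling: days per prey;
    gamma: foraging-initiation threshold (ind/L), 0 for type II; n: shape
    exponent, 1 for type II.
    """

    attack: float
    handling: float = 0.0
    gamma: float = 0.0
    n: float = 1.0
    type: str = "II"

    def __post_init__(self) -> None:
        if self.attack <= 0:
            raise InvalidRateError("attack must be > 0")
        if self.handling < 0 or self.gamma < 0:
            raise InvalidRateError("handling and gamma must be >= 0")
        if self.n < 1:
            raise InvalidRateError("n must be >= 1")
        if self.type == "II" and not (self.gamma == 0 and self.n == 1):
            raise InvalidRateError("type II requires gamma = 0 and n = 1")
        if self.type not in ("II", "III"):
            raise InvalidRateError("type must be 'II' or 'III'")


@dataclass(frozen=True)
class MortalityParams:
    """Background longevity (days), predator exposure density (predators/L)
    and fish foraging swim speed (cm/s)."""

    longevity: float = 50.0
    predator_density: float = 4.1e-6
    swim_speed: float = 5.62

    def __post_init__(self) -> None:
        if self.longevity <= 0:
            raise InvalidRateError("longevity must be > 0")
        if self.predator_density < 0:
            raise InvalidRateError("predator_density must be >= 0")


@dataclass(frozen=True)
class PerceptionParams:
    """Relative detection thresholds for food and light differences.

    A difference smaller than the threshold fraction of the current-sector
    value is imperceptible when assessing an adjacent sector.
    """

    ae_food: float = 0.19
    ae_light: float = 0.10

    def __post_init__(self) -> None:
        if self.ae_food < 0 or self.ae_light < 0:
            raise InvalidRateError("perception thresholds must be >= 0")


def growth_rate(
    food: float,
    density: float,
    light: float,
    age: str,
    kairomone: bool,
    p: GrowthParams,
) -> float:
    """Somatic growth rate (per day) at the given local conditions.

    Saturating (Monod) in food, linearly decreasing in conspecific density
    and in log10(1+light); the light cost is steeper for adults; predator
    cues impose a flat cost.  May be negative under crowding or darkness
    costs; callers rank such states via :func:`fitness`.
    """
    light_cost = (p.c + (p.u if age == ADULT else 0.0)) * np.log10(1.0 + light)
    return (
        p.g0
        + p.a1 * food / (p.a2 + food)
        - p.b * density
        - light_cost
        - (p.kappa if kairomone else 0.0)
    )


def reaction_distance(light: float, bands, age: str, p: RDParams) -> float:
    """Visual reaction distance of the fish toward one prey age class (cm)."""
    base = p.r0 + p.k * np.log10(1.0 + light) + (p.l if age == ADULT else 0.0)
    return max(0.0, base * p.band_factor(bands))


def attack_rate(rd: float, v: float) -> float:
    """Clearance rate (L per predator per day) from reaction distance.

    A fish cruising at v (cm/s) sweeps a cylinder of radius rd (cm):
    pi * rd^2 * v cm^3/s = pi * rd^2 * v * 86400 / 1000 L/day.
    """
    if rd < 0 or v < 0:
        raise InvalidRateError("rd and v must be >= 0")
    return np.pi * rd * rd * v * 86400.0 / 1000.0


def consumption_rate(N, p: FunctionalResponseParams):
    """Predator consumption rate (prey per predator per day) at prey
    density N (ind/L).  Threshold disc equation: with M = max(N - gamma, 0),
    C = a M^n / (1 + a h M^n).  gamma = 0, n = 1 recovers Holling's type II
    disc equation exactly.
    """
    N = np.asarray(N, dtype=float)
    M = np.maximum(N - p.gamma, 0.0)
    Mn = M**p.n
    out = p.attack * Mn / (1.0 + p.attack * p.handling * Mn)
    return out if out.ndim else float(out)


def per_capita_fish_mortality(
    N, p: FunctionalResponseParams, predator_density: float
) -> float:
    """Per-capita predation mortality (per day): P * C(N) / N.

    At N = 0 the continuous limit is returned: P*a for type II (gamma = 0,
    n = 1), 0 otherwise.  Type II risk declines monotonically with density
    (dilution); type III is zero below gamma and unimodal above it, giving
    prey both a low- and a high-density refuge.
    """
    N = np.asarray(N, dtype=float)
    scalar = N.ndim == 0
    N = np.atleast_1d(N)
    if (N < 0).any():
        raise InvalidRateError("prey density must be >= 0")
    out = np.empty_like(N)
    pos = N > 0
    out[pos] = predator_density * consumption_rate(N[pos], p) / N[pos]
    limit = predator_density * p.attack if (p.gamma == 0 and p.n == 1) else 0.0
    out[~pos] = limit
    return float(out[0]) if scalar else out


def total_mortality(fish_mort: float, p: MortalityParams) -> float:
    """Total per-capita mortality: predation plus background 1/longevity."""
    if fish_mort < 0:
        raise InvalidRateError("fish mortality must be >= 0")
    return fish_mort + 1.0 / p.longevity


def fitness(gr: float, mort: float, longevity: float = 50.0) -> float:
    """Growth-to-mortality fitness score (Werner-Gilliam ratio).

    For gr > 0 this is gr/mort.  For gr <= 0 the ratio is misleading (a
    higher mortality would *raise* it), so such states are scored gr *
    longevity: a non-positive number ranking them by growth alone, always
    below any positive-growth state.
    """
    if mort <= 0:
        raise InvalidRateError("mortality must be > 0")
    if gr > 0:
        return gr / mort
    return gr * longevity


def calibrate_predator_density(
    light_mid: float,
    bands,
    rd: RDParams,
    mort: MortalityParams,
    age: str = JUVENILE,
) -> float:
    """Predator exposure density such that the low-density type II fish
    mortality at mid-column light equals background mortality 1/longevity.

    No fish were physically present in the verification columns; risk is
    information, so the exposure scale is a free parameter anchored to the
    background rate.
    """
    a = attack_rate(reaction_distance(light_mid, bands, age, rd), mort.swim_speed)
    if a == 0:
        raise InvalidRateError("attack rate is zero at the calibration light")
    return (1.0 / mort.longevity) / a
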