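"""One-compartment alveolar burden kinetics with constant clearance.

The alveolar region is a single well-mixed compartment: particles deposit at
a constant rate D and are cleared first-order at rate k = ln2/t_half, so

    dB/dt = D - k B,   B(0) = 0
    B(t)  = (D/k) (1 - exp(-k t)),   B_ss = D/k.

The steady-state identity B_ss = D/k is the backbone of both translation
models; this module also inverts it, turning a critical (threshold) burden
into the exposure concentration that just attains it — a NOAEC.

Clearance rates are computed exactly as ln2/t_half everywhere; rounded rates
such as "0.01/day for a 60-day half-time" are never substituted, since a
rounded intermediate shifts derived concentrations by ~15 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .quantities import Q, Quantity

__all__ = [
    "ClearanceSpec",
    "BurdenState",
    "rate_from_half_time",
    "deposition_rate",
    "steady_state_burden",
    "burden_trajectory",
    "noaec_from_threshold",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ClearanceSpec:
    """First-order clearance, stated as half-time and rate (k t_half = ln2)."""

    half_time: Quantity   # days
    rate: Quantity        # 1/day

    def __post_init__(self):
        prod = float(self.rate * self.half_time)
        if not math.isclose(prod, _LN2, rel_tol=1e-12):
            raise ValueError(
                f"rate x half_time = {prod!r} but must equal ln(2); "
                "construct with ClearanceSpec.from_half_time")

    @classmethod
    def from_half_time(cls, half_time: Quantity) -> "ClearanceSpec":
        return cls(half_time=half_time.to("day"),
                   rate=rate_from_half_time(half_time))


@dataclass(frozen=True)
class BurdenState:
    """Deposition rate, steady-state burden and an optional trajectory."""

    deposition_rate: Quantity
    steady_state_burden: Quantity
    trajectory: Optional[tuple[np.ndarray, np.ndarray]] = None  # (days, burden)


def rate_from_half_time(half_time: Quantity) -> Quantity:
    """k = ln2 / t_half [1/day]."""
    if half_time.canonical <= 0:
        raise ValueError("half-time must be positive")
    t = half_time.magnitude_in("day")
    return Q(_LN2 / t, "1/day")


def deposition_rate(concentration: Quantity, alveolar_fraction: float,
                    ventilation: Quantity,
                    density: Optional[Quantity] = None) -> Quantity:
    """Alveolar deposition rate: C x F_a x VE, optionally / density.

    Without a density the result is a mass rate [mg/day]; with one it is the
    particle *volume* deposition rate [ul/day] that the volumetric model uses.
    ``ventilation`` may be absolute (m^3/day) or per-kg (m^3/(day*kg)); the
    result is then per kg as well.
    """
    if concentration.canonical < 0:
        raise ValueError("concentration must be non-negative")
    if not 0 < alveolar_fraction < 1:
        raise ValueError("alveolar fraction must lie in (0, 1)")
    if ventilation.canonical <= 0:
        raise ValueError("ventilation must be positive")
    rate = concentration * alveolar_fraction * ventilation
    if density is None:
        return rate
    if density.canonical <= 0:
        raise ValueError("density must be positive")
    return rate / density


def steady_state_burden(dep_rate: Quantity, clearance: ClearanceSpec) -> Quantity:
    """Equilibrium burden B_ss = deposition rate / clearance rate."""
    if clearance.rate.canonical <= 0:
        raise ValueError("clearance rate must be positive: no steady state")
    if dep_rate.canonical < 0:
        raise ValueError("deposition rate must be non-negative")
    return dep_rate / clearance.rate


def burden_trajectory(dep_rate: Quantity, clearance: ClearanceSpec,
                      times: Sequence[float] | np.ndarray) -> BurdenState:
    """Analytic build-up B(t) = (D/k)(1 - e^{-kt}) from a clean lung.

    ``times`` are days, non-negative and strictly increasing.  The analytic
    solution is exact; the test-suite cross-checks it against independent
    numeric integration of dB/dt = D - kB.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    bss = steady_state_burden(dep_rate, clearance)
    k = clearance.rate.magnitude_in("1/day")
    burden = bss.magnitude * (1.0 - np.exp(-k * t))
    return BurdenState(deposition_rate=dep_rate, steady_state_burden=bss,
                       trajectory=(t, burden))


def noaec_from_threshold(threshold_burden: Quantity, clearance: ClearanceSpec,
                         ventilation: Quantity, alveolar_fraction: float,
                         density: Optional[Quantity] = None) -> Quantity:
    """Concentration whose steady-state burden equals a threshold burden.

    Inverse of ``steady_state_burden(deposition_rate(.))``:

        NOAEC = threshold x (density if volumetric) x k / (VE x F_a)

    With a volume threshold per kg and per-kg ventilation the body-weight
    normalization cancels and the result is a plain air concentration.
    """
    if threshold_burden.canonical < 0:
        raise ValueError("threshold burden must be non-negative")
    if not 0 < alveolar_fraction < 1:
        raise ValueError("alveolar fraction must lie in (0, 1)")
    if ventilation.canonical <= 0:
        raise ValueError("ventilation must be positive")
    numerator = threshold_burden * clearance.rate
    if density is not None:
        if density.canonical <= 0:
            raise ValueError("density must be positive")
        numerator = numerator * density
    noaec = numerator / (ventilation * alveolar_fraction)
    return noaec.to("mg/m^3")
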