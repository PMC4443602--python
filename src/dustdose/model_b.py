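"""Volumetric translation: retained particle volume per macrophage pool.

The effect metric is the retained particle *volume* relative to the total
alveolar-macrophage pool volume, assumed equipotent across species.  The
classical Morrow criterion puts overload onset at a retained volume of 6 %
of the pool (rat pool 70 ul/kg -> 4.2 ul/kg).  Under one-compartment
steady-state kinetics the rat NOAEC follows by inverting B_ss = D/k, and a
human equivalent concentration follows from two multiplicative adjustment
factors:

    AF_lungburden = (VE_rat F_rat) / (VE_human F_human)      (per kg)
    AF_clearance  = (t_half_human / t_half_rat)
                    x (pool_rat / pool_human)                 (per kg)
    HEC           = NOAEC x AF_lungburden / AF_clearance

These closed forms are exactly the decomposition of the full steady-state
burden-per-pool equivalence ratio; :func:`hec_volumetric` recomputes the
full ratio independently and aborts if the decomposition ever disagrees.

All volumetric bookkeeping is normalized per kg body weight on both species
(the historical equation mixed a per-g-lung threshold with per-kg
ventilation; both the 1 ul/kg and the corrected 4.2 ul/kg thresholds are
first-class scenario inputs, differing by the reported factor 4.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .kinetics import ClearanceSpec, noaec_from_threshold
from .physiology import SpeciesPhysiology
from .quantities import CONCENTRATION, Q, Quantity, assert_dimension

__all__ = [
    "ModelBScenario",
    "TranslationResult",
    "morrow_threshold",
    "threshold_per_gram_lung",
    "noaec_eq7",
    "af_lungburden",
    "af_clearance",
    "hec_volumetric",
    "hec_simple_rule",
    "MORROW_POOL_FRACTION",
]

#: classical overload-onset criterion: 6 % of the macrophage pool volume
MORROW_POOL_FRACTION = 0.06


@dataclass(frozen=True)
class TranslationResult:
    """A NOAEC -> HEC translation with its full calculation ledger."""

    noaec_rat: Quantity             # mg/m^3
    af_lungburden: float
    af_clearance: float
    hec: Quantity                   # mg/m^3
    ledger: list = field(default_factory=list)  # (label, value, provenance)
    dimension_audit_clean: bool = True

    def __post_init__(self):
        expected = self.noaec_rat.magnitude_in("mg/m^3") * \
            self.af_lungburden / self.af_clearance
        if not math.isclose(self.hec.magnitude_in("mg/m^3"), expected,
                            rel_tol=1e-10):
            raise ValueError("HEC does not equal NOAEC x AF_lb / AF_cl")


@dataclass(frozen=True)
class ModelBScenario:
    """One complete input row for a volumetric translation."""

    rat: SpeciesPhysiology
    human: SpeciesPhysiology
    rat_alveolar_fraction: float
    human_alveolar_fraction: float
    threshold_volume_per_kg: Quantity    # ul/kg
    particle_density: Quantity           # g/cm^3
    fvi: float = 1.0                     # undocumented divisor; 1 reproduces all outputs
    mppd_version_label: str = ""
    label: str = ""

    def __post_init__(self):
        for name, f in (("rat_alveolar_fraction", self.rat_alveolar_fraction),
                        ("human_alveolar_fraction", self.human_alveolar_fraction)):
            if not 0 < f < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.threshold_volume_per_kg.canonical <= 0:
            raise ValueError("threshold volume must be positive")
        if self.particle_density.canonical <= 0:
            raise ValueError("particle density must be positive")
        if self.fvi <= 0:
            raise ValueError("fvi must be positive")


def morrow_threshold(pool_per_kg: Quantity,
                     fraction: float = MORROW_POOL_FRACTION) -> Quantity:
    """Overload-onset burden: a fixed fraction of the macrophage pool volume.

    6 % of the 70 ul/kg rat pool is 4.2 ul/kg.
    """
    if pool_per_kg.canonical <= 0:
        raise ValueError("pool volume must be positive")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    return (pool_per_kg * fraction).to("ul/kg")


def threshold_per_gram_lung(threshold_per_kg: Quantity,
                            lung_mass_per_kg: Quantity) -> Quantity:
    """Re-express a per-kg-body-weight volume threshold per gram of lung.

    4.2 ul/kg over 4.5 g lung per kg gives 0.93 ul/g — the 'about 1 ul per
    g lung' figure whose unit was historically conflated with per-kg.
    """
    if threshold_per_kg.canonical <= 0 or lung_mass_per_kg.canonical <= 0:
        raise ValueError("inputs must be positive")
    return (threshold_per_kg / lung_mass_per_kg).to("ul/g")


def noaec_eq7(s: ModelBScenario) -> Quantity:
    """Rat NOAEC from the volumetric threshold under steady-state kinetics.

    threshold x density x k_rat / (VE_rat x F_rat) / fvi, everything per kg
    body weight.  The clearance rate is implicit in the historical equation
    (ln2/60 per day for the rat); it is explicit here.
    """
    clearance = ClearanceSpec.from_half_time(s.rat.clearance_half_time)
    noaec = noaec_from_threshold(
        threshold_burden=s.threshold_volume_per_kg,
        clearance=clearance,
        ventilation=s.rat.ventilation_rate_per_kg,
        alveolar_fraction=s.rat_alveolar_fraction,
        density=s.particle_density,
    )
    return noaec / s.fvi


def af_lungburden(s: ModelBScenario) -> float:
    """Species ratio of deposited dose per kg: (VE_r F_r)/(VE_h F_h)."""
    denom = s.human.ventilation_rate_per_kg * s.human_alveolar_fraction
    if denom.canonical == 0:
        raise ValueError("human ventilation x fraction must be nonzero")
    return float((s.rat.ventilation_rate_per_kg * s.rat_alveolar_fraction)
                 / denom)


def af_clearance(s: ModelBScenario) -> float:
    """Species ratio of clearance-weighted pool capacity.

    (t_half_human / t_half_rat) x (pool_rat / pool_human), per kg.
    """
    return float((s.human.clearance_half_time / s.rat.clearance_half_time)
                 * (s.rat.macrophage_pool_volume_per_kg
                    / s.human.macrophage_pool_volume_per_kg))


def _full_burden_per_pool_ratio(s: ModelBScenario) -> float:
    """Steady-state burden-per-pool ratio computed without the AF shortcut.

    For unit inhaled concentration, species X retains per kg
    B_X = VE_X F_X / k_X at steady state; relative to its pool the species
    ratio (rat / human) is the exact translation factor the AF decomposition
    must reproduce.
    """
    k_r = ClearanceSpec.from_half_time(s.rat.clearance_half_time).rate
    k_h = ClearanceSpec.from_half_time(s.human.clearance_half_time).rate
    rat_side = (s.rat.ventilation_rate_per_kg * s.rat_alveolar_fraction
                / (k_r * s.rat.macrophage_pool_volume_per_kg))
    human_side = (s.human.ventilation_rate_per_kg * s.human_alveolar_fraction
                  / (k_h * s.human.macrophage_pool_volume_per_kg))
    return float(rat_side / human_side)


def hec_volumetric(s: ModelBScenario) -> TranslationResult:
    """Full volumetric translation NOAEC -> HEC with consistency check.

    The AF decomposition is verified against the independent full
    steady-state burden-per-pool ratio to 1e-10 relative; disagreement is a
    programming error and aborts.
    """
    noaec = noaec_eq7(s)
    af_lb = af_lungburden(s)
    af_cl = af_clearance(s)
    full_ratio = _full_burden_per_pool_ratio(s)
    if not math.isclose(af_lb / af_cl, full_ratio, rel_tol=1e-10):
        raise ArithmeticError(
            "AF decomposition disagrees with the full steady-state "
            f"burden-per-pool ratio: {af_lb / af_cl!r} vs {full_ratio!r}")
    hec = noaec * af_lb / af_cl
    audit = assert_dimension(hec, "concentration")
    ledger = [
        ("threshold_volume_per_kg", s.threshold_volume_per_kg,
         "critical steady-state particle volume burden"),
        ("particle_density", s.particle_density, "substance density"),
        ("rat_alveolar_fraction", s.rat_alveolar_fraction,
         f"alveolar deposition fraction, rat ({s.mppd_version_label})"),
        ("human_alveolar_fraction", s.human_alveolar_fraction,
         f"alveolar deposition fraction, human ({s.mppd_version_label})"),
        ("rat_half_time", s.rat.clearance_half_time,
         s.rat.provenance.get("clearance_half_time", "")),
        ("human_half_time", s.human.clearance_half_time,
         s.human.provenance.get("clearance_half_time", "")),
        ("noaec_rat", noaec, "threshold x density x k / (VE x F), per kg"),
        ("af_lungburden", af_lb, "(VE_r F_r)/(VE_h F_h)"),
        ("af_clearance", af_cl, "(t1/2_h/t1/2_r) x (pool_r/pool_h)"),
        ("hec", hec, "NOAEC x AF_lungburden / AF_clearance"),
    ]
    return TranslationResult(noaec_rat=noaec, af_lungburden=af_lb,
                             af_clearance=af_cl, hec=hec, ledger=ledger,
                             dimension_audit_clean=bool(audit))


def hec_simple_rule(density: Quantity) -> Quantity:
    """The published density-proportional shortcut: HEC = 0.5 x density.

    Kept as a labelled reference line for comparisons; numerically it sets
    the HEC [mg/m^3] to half the density magnitude [g/cm^3].
    """
    if density.canonical <= 0:
        raise ValueError("density must be positive")
    return Q(0.5 * density.magnitude_in("g/cm^3"), "mg/m^3")
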