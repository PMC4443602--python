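"""Provenance-tagged species physiology and cross-species scaling.

Holds the physiological constants the translation models consume —
ventilation rates, alveolar surface areas, alveolar-macrophage pool sizes,
clearance half-times, lung masses — each tagged with a citation string so a
derived exposure limit can be audited back to its inputs.  Ships a registry
of named presets (rat and human variants differing in surface-area source
and clearance half-time) plus the two derivations that feed the mass-based
translation: the human/rat surface-area ratio and quarter-power allometric
scaling of clearance.

Ventilation rates are daily exposure-period volumes exactly as the source
data state them (rat 0.29 m³/day/kg already encodes a 6-h exposure day;
human 10 m³/day encodes one shift); no additional weekly schedule adjustment
is applied by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .quantities import Q, Quantity

__all__ = [
    "ParameterValue",
    "SpeciesPhysiology",
    "macrophage_pool_volume",
    "allometric_half_time",
    "surface_translation_factor",
    "load_physiology",
    "available_presets",
]


@dataclass(frozen=True)
class ParameterValue:
    """A quantity plus the provenance trail that justifies it."""

    quantity: Quantity
    source: str
    method: str = ""
    notes: str = ""

    def __post_init__(self):
        if not self.source:
            raise ValueError("every registry parameter needs a non-empty source")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Complete physiological parameter set for one species/strain/source.

    Pool consistency: when both a macrophage count and a cell volume are
    given, the stated pool volume must equal their product within 1 %.
    """

    species_strain: str
    body_weight: Quantity                   # kg
    ventilation_rate_per_kg: Quantity       # m^3/(day*kg)
    alveolar_surface_area: Quantity         # m^2
    dead_space_fraction: float
    macrophage_pool_volume_per_kg: Quantity  # ul/kg
    clearance_half_time: Quantity           # days
    macrophage_count_per_kg: Optional[float] = None
    macrophage_cell_volume: Optional[Quantity] = None  # um^3
    lung_mass_per_kg: Optional[Quantity] = None        # g/kg
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("body_weight", "ventilation_rate_per_kg",
                     "alveolar_surface_area", "macrophage_pool_volume_per_kg",
                     "clearance_half_time"):
            q: Quantity = getattr(self, name)
            if q.canonical <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.dead_space_fraction < 1:
            raise ValueError("dead_space_fraction must lie in [0, 1)")
        if self.macrophage_count_per_kg is not None and self.macrophage_cell_volume is not None:
            derived = macrophage_pool_volume(
                self.macrophage_count_per_kg, self.macrophage_cell_volume)
            stated = self.macrophage_pool_volume_per_kg.magnitude_in("ul/kg")
            if not math.isclose(derived.magnitude_in("ul/kg"), stated, rel_tol=0.01):
                raise ValueError(
                    "stated macrophage pool volume "
                    f"({stated:g} ul/kg) disagrees with count x cell volume "
                    f"({derived.magnitude_in('ul/kg'):g} ul/kg) by more than 1%")

    @property
    def ventilation_rate(self) -> Quantity:
        """Absolute daily ventilation for this animal/person [m^3/day]."""
        return (self.ventilation_rate_per_kg * self.body_weight).to("m^3/day")

    @property
    def clearance_rate(self) -> Quantity:
        """First-order alveolar clearance rate ln2 / t_half [1/day]."""
        from .kinetics import rate_from_half_time
        return rate_from_half_time(self.clearance_half_time)


def macrophage_pool_volume(count_per_kg: float, cell_volume: Quantity) -> Quantity:
    """Total alveolar-macrophage pool volume per kg body weight [ul/kg].

    E.g. the rat pool: 6e7 cells/kg x 1166 um^3/cell = 69.96 ~ 70 ul/kg.
    """
    if count_per_kg <= 0:
        raise ValueError("macrophage count must be positive")
    if cell_volume.canonical <= 0:
        raise ValueError("macrophage cell volume must be positive")
    per_kg = cell_volume * count_per_kg / Q(1, "kg")
    return per_kg.to("ul/kg")


def allometric_half_time(t_half_rat: Quantity, bw_rat: Quantity,
                         bw_human: Quantity) -> Quantity:
    """Scale a rat clearance half-time to humans by quarter-power allometry.

    Rates scale as (BW_rat/BW_human)^(1/4) (West et al. scaling), and
    half-times inversely to rates:

        t_half_human = t_half_rat / (BW_rat/BW_human)^(1/4)

    60 days at 0.25/70 kg gives 245.5 days, supporting the ~255-day estimate
    from two-compartment human retention modelling.
    """
    for name, q in (("t_half_rat", t_half_rat), ("bw_rat", bw_rat),
                    ("bw_human", bw_human)):
        if q.canonical <= 0:
            raise ValueError(f"{name} must be positive")
    ratio = (bw_rat / bw_human) ** 0.25
    return (t_half_rat / ratio).to("day")


def surface_translation_factor(s_human: Quantity, s_rat: Quantity) -> float:
    """Dimensionless human/rat alveolar surface-area ratio.

    193 for the Brown-based areas (57.22/0.2972); 349 for the reference-method
    areas (143/0.41).
    """
    if s_rat.canonical <= 0 or s_human.canonical <= 0:
        raise ValueError("surface areas must be positive")
    return float(s_human / s_rat)


def _load_presets() -> dict:
    text = resources.files("dustdose.data").joinpath(
        "physiology_presets.json").read_text()
    return json.loads(text)


_PRESETS = _load_presets()


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def load_physiology(preset_name: str) -> SpeciesPhysiology:
    """Materialize a named physiology preset with provenance strings."""
    try:
        raw = _PRESETS[preset_name]
    except KeyError:
        raise KeyError(
            f"unknown physiology preset {preset_name!r}; "
            f"available: {', '.join(available_presets())}") from None
    return SpeciesPhysiology(
        species_strain=raw["species_strain"],
        body_weight=Q(raw["body_weight_kg"], "kg"),
        ventilation_rate_per_kg=Q(raw["ventilation_rate_per_kg_m3_day_kg"],
                                  "m^3/(day*kg)"),
        alveolar_surface_area=Q(raw["alveolar_surface_area_m2"], "m^2"),
        dead_space_fraction=raw["dead_space_fraction"],
        macrophage_count_per_kg=raw.get("macrophage_count_per_kg"),
        macrophage_cell_volume=(
            Q(raw["macrophage_cell_volume_um3"], "um^3")
            if raw.get("macrophage_cell_volume_um3") is not None else None),
        macrophage_pool_volume_per_kg=Q(
            raw["macrophage_pool_volume_per_kg_ul_kg"], "ul/kg"),
        clearance_half_time=Q(raw["clearance_half_time_days"], "day"),
        lung_mass_per_kg=(Q(raw["lung_mass_per_kg_g_kg"], "g/kg")
                          if raw.get("lung_mass_per_kg_g_kg") is not None else None),
        provenance=raw.get("provenance", {}),
    )
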