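"""Mass-per-surface translation: retained particle mass per alveolar surface.

The effect metric is the steady-state retained particle *mass* per square
metre of alveolar epithelial surface, assumed equipotent across species.
Equating that metric at the rat NOAEC and at the human HEC and solving,

    HEC = NOAEC x [F_r VE_r / (k_r S_r)] / [F_h VE_h / (k_h S_h)],

with absolute ventilations (per animal / per person), clearance rates
k = ln2/t_half and alveolar surfaces S.  Nothing in this expression involves
the substance density: a mass deposited, mass cleared, mass retained model
is density-blind by construction, so a post-hoc division of the resulting
HEC by the density in g/cm^3 is dimensionally not a concentration at all.
:func:`density_division_audit` performs that division through the unit layer
and reports both the dimensionless honest value and the unit-dropping
magnitude that circulates in the literature.

:func:`corrected_hec` applies revised surface-area and clearance inputs to a
published HEC as multiplicative corrections
(surface_new/surface_old) x (t_half_old/t_half_new).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .deposition import DepositionProfile
from .kinetics import ClearanceSpec
from .model_b import TranslationResult
from .physiology import SpeciesPhysiology
from .quantities import DimensionReport, Q, Quantity, assert_dimension

__all__ = [
    "ModelAScenario",
    "DensityAudit",
    "hec_mass_per_surface",
    "corrected_hec",
    "density_division_audit",
    "REFERENCE_HECS",
]

#: Published mass-per-surface HECs (mg/m^3) kept as labelled reference
#: constants; the underlying deposition runs are documented as
#: irreproducible, so these are inputs, never recomputed.
REFERENCE_HECS = {
    "toner": (0.133, 0.134),
    "TiO2": (1.02, 1.06, 1.07),
}


@dataclass(frozen=True)
class ModelAScenario:
    """Inputs for one mass-per-surface translation."""

    rat: SpeciesPhysiology
    human: SpeciesPhysiology
    rat_deposition: DepositionProfile
    human_deposition: DepositionProfile
    noaec_rat: Quantity                    # mg/m^3
    substance_label: str = ""
    substance_density: Optional[Quantity] = None  # metadata only, never used

    def __post_init__(self):
        if self.noaec_rat.canonical <= 0:
            raise ValueError("NOAEC must be positive")


@dataclass(frozen=True)
class DensityAudit:
    """Outcome of dividing a concentration by a material density."""

    honest_value: Quantity          # dimensionless, computed through units
    dimension_report: DimensionReport
    unit_dropping_magnitude: float  # magnitudes divided, units discarded

    @property
    def dimension_ok(self) -> bool:
        return self.dimension_report.ok


def hec_mass_per_surface(s: ModelAScenario) -> TranslationResult:
    """Translate a rat NOAEC by equating retained mass per unit surface.

    Returns a :class:`TranslationResult` whose adjustment factors decompose
    the translation as HEC = NOAEC x AF_lungburden / AF_clearance with
    AF_lungburden = (F_r VE_r)/(F_h VE_h) (absolute ventilations) and
    AF_clearance = (t_half_h S_r)/(t_half_r S_h) x ... i.e. (k_r S_r)/(k_h S_h).
    The result is independent of ``substance_density`` by construction.
    """
    f_r = s.rat_deposition.alveolar_fraction
    f_h = s.human_deposition.alveolar_fraction
    ve_r = s.rat.ventilation_rate
    ve_h = s.human.ventilation_rate
    k_r = ClearanceSpec.from_half_time(s.rat.clearance_half_time).rate
    k_h = ClearanceSpec.from_half_time(s.human.clearance_half_time).rate
    af_lb = float((ve_r * f_r) / (ve_h * f_h))
    af_cl = float((k_r * s.rat.alveolar_surface_area)
                  / (k_h * s.human.alveolar_surface_area))
    hec = (s.noaec_rat * af_lb / af_cl).to("mg/m^3")
    audit = assert_dimension(hec, "concentration")
    ledger = [
        ("noaec_rat", s.noaec_rat, f"rat NOAEC, {s.substance_label}"),
        ("rat_deposition", f_r, s.rat_deposition.source_note),
        ("human_deposition", f_h, s.human_deposition.source_note),
        ("rat_surface", s.rat.alveolar_surface_area,
         s.rat.provenance.get("alveolar_surface_area", "")),
        ("human_surface", s.human.alveolar_surface_area,
         s.human.provenance.get("alveolar_surface_area", "")),
        ("af_lungburden", af_lb, "(F_r VE_r)/(F_h VE_h), absolute"),
        ("af_clearance", af_cl, "(k_r S_r)/(k_h S_h)"),
        ("hec", hec, "mass per alveolar surface equated across species"),
    ]
    return TranslationResult(noaec_rat=s.noaec_rat, af_lungburden=af_lb,
                             af_clearance=af_cl, hec=hec, ledger=ledger,
                             dimension_audit_clean=bool(audit))


def corrected_hec(hec_reference: Quantity, surface_ratio_old: float,
                  surface_ratio_new: float, half_time_old: Quantity,
                  half_time_new: Quantity) -> Quantity:
    """Re-derive a published HEC under revised surface and clearance inputs.

    HEC' = HEC x (surface_ratio_new / surface_ratio_old)
               x (t_half_old / t_half_new)

    A larger human surface raises the tolerable human concentration; a
    shorter human half-time (faster clearance) raises it as well.  With
    ratios 349/193 and 400/255 days: 0.134 -> 0.380 and 1.07 -> 3.04 mg/m^3.
    """
    for name, v in (("hec_reference", hec_reference.canonical),
                    ("surface_ratio_old", surface_ratio_old),
                    ("surface_ratio_new", surface_ratio_new),
                    ("half_time_old", half_time_old.canonical),
                    ("half_time_new", half_time_new.canonical)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    factor = (surface_ratio_new / surface_ratio_old) * \
        float(half_time_old / half_time_new)
    return (hec_reference * factor).to("mg/m^3")


def density_division_audit(hec: Quantity, density: Quantity) -> DensityAudit:
    """Divide a HEC by a material density and audit the dimension.

    Performed through the unit layer, mg/m^3 over g/cm^3 cancels completely:
    1.06 mg/m^3 / 4.3 g/cm^3 = 2.465e-10, a pure number that is *not* a
    concentration.  The audit also records the unit-dropping magnitude
    (1.06/4.3 = 0.25) that results from dividing the printed numbers and
    keeping the mg/m^3 label.
    """
    if hec.canonical <= 0 or density.canonical <= 0:
        raise ValueError("inputs must be positive")
    honest = hec / density
    report = assert_dimension(honest, "concentration")
    unit_dropping = hec.magnitude_in("mg/m^3") / density.magnitude_in("g/cm^3")
    return DensityAudit(honest_value=honest, dimension_report=report,
                        unit_dropping_magnitude=unit_dropping)
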