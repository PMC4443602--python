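"""Tabulated regional deposition fractions and extrathoracic corrections.

Alveolar deposition fractions are *inputs*, not physics: they come from runs
of the MPPD multiple-path particle dosimetry program, and the bundled table
records every variant the dosimetry literature in scope reports — program
version 2.0 vs 2.11, inhalability adjustment on/off for the rat, the two
human oronasal breathing patterns, a substance-density sweep, and
substance-specific human fractions for toner and pigmentary TiO2.  The table
is keyed exactly; an unknown scenario fails loudly rather than interpolating,
because differences between program versions/settings of a factor ~2 are
precisely what the sensitivity grid is about.

Fractions are stored as numbers in (0, 1); rendering multiplies by 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .quantities import Q, Quantity

__all__ = [
    "DepositionProfile",
    "lookup_deposition",
    "deposition_table",
    "extrathoracic_correction",
    "first_derivation_chain",
]


@dataclass(frozen=True)
class DepositionProfile:
    """One tabulated deposition scenario with provenance."""

    program_version: str
    species: str
    breathing_pattern: str
    inhalability_adjustment: str          # "on" / "off" / "n/a"
    alveolar_fraction: float
    substance: str = "generic"
    particle_mmad: Optional[Quantity] = None      # um
    particle_gsd: Optional[float] = None
    particle_density: Optional[Quantity] = None   # g/cm^3
    head_tb_fraction: Optional[float] = None
    source_note: str = ""

    def __post_init__(self):
        if not 0 < self.alveolar_fraction < 1:
            raise ValueError("alveolar fraction must lie in (0, 1)")
        if self.head_tb_fraction is not None:
            if not 0 <= self.head_tb_fraction < 1:
                raise ValueError("head/TB fraction must lie in [0, 1)")
            if self.alveolar_fraction + self.head_tb_fraction > 1:
                raise ValueError("regional fractions must sum to at most 1")

    @property
    def alveolar_percent(self) -> float:
        return 100 * self.alveolar_fraction


def _load_table() -> pd.DataFrame:
    with resources.files("dustdose.data").joinpath(
            "deposition_fractions.csv").open() as fh:
        return pd.read_csv(fh)


_TABLE = _load_table()

_KEY_COLUMNS = ("program_version", "species", "breathing_pattern",
                "inhalability_adjustment", "substance", "mmad_um", "gsd",
                "density_g_cm3")


def deposition_table(extra: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """The bundled deposition table (a copy), optionally with user rows appended."""
    if extra is None:
        return _TABLE.copy()
    return pd.concat([_TABLE, extra], ignore_index=True)


def _row_to_profile(row: pd.Series) -> DepositionProfile:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    mmad = _opt(row["mmad_um"])
    density = _opt(row["density_g_cm3"])
    return DepositionProfile(
        program_version=row["program_version"],
        species=row["species"],
        breathing_pattern=row["breathing_pattern"],
        inhalability_adjustment=row["inhalability_adjustment"],
        substance=row["substance"],
        particle_mmad=Q(mmad, "um") if mmad is not None else None,
        particle_gsd=_opt(row["gsd"]),
        particle_density=Q(density, "g/cm^3") if density is not None else None,
        alveolar_fraction=float(row["alveolar_fraction"]),
        head_tb_fraction=_opt(row["head_tb_fraction"]),
        source_note=row.get("source_note", ""),
    )


def lookup_deposition(table: Optional[pd.DataFrame] = None,
                      **key) -> DepositionProfile:
    """Exact-key lookup of a tabulated deposition profile.

    Keys are any of: program_version, species, breathing_pattern,
    inhalability_adjustment, substance, mmad_um, gsd, density_g_cm3.
    The supplied keys must select exactly one row; zero matches raise a
    lookup error that suggests the nearest rows (no interpolation, ever).
    """
    df = _TABLE if table is None else table
    unknown = set(key) - set(_KEY_COLUMNS)
    if unknown:
        raise KeyError(f"unknown lookup keys {sorted(unknown)}; "
                       f"valid keys: {_KEY_COLUMNS}")
    mask = pd.Series(True, index=df.index)
    for col, value in key.items():
        if isinstance(value, (int, float)):
            mask &= df[col].apply(
                lambda v: not pd.isna(v) and math.isclose(float(v), float(value)))
        else:
            mask &= df[col] == value
    hits = df[mask]
    if len(hits) == 1:
        return _row_to_profile(hits.iloc[0])
    if len(hits) > 1:
        raise KeyError(
            f"deposition key {key} is ambiguous ({len(hits)} rows); "
            "add more keys")
    # zero matches: suggest rows that agree on the categorical keys
    nearest = df
    for col in ("species", "program_version"):
        if col in key:
            sub = nearest[nearest[col] == key[col]]
            if len(sub):
                nearest = sub
    suggestions = nearest[list(_KEY_COLUMNS)].to_dict("records")[:5]
    raise KeyError(
        f"no tabulated deposition profile for {key}; this table never "
        f"interpolates. Nearest available keys: {suggestions}")


def extrathoracic_correction(head_tb_fraction: float) -> float:
    """Inflate an alveolar-referenced concentration to inhaled air.

    A fraction f of inhaled dust deposits in the head and tracheo-bronchial
    region, so the inhaled concentration exceeds the thoracic-delivery one by
    1/(1-f): f = 0.25 gives 4/3, f = 1/3 gives 3/2.
    """
    if not 0 <= head_tb_fraction < 1:
        raise ValueError("head/TB fraction must lie in [0, 1)")
    return 1.0 / (1.0 - head_tb_fraction)


def first_derivation_chain(ventilation_per_kg: Quantity,
                           dead_space_fraction: float,
                           critical_alveolar_volume_rate: Quantity,
                           head_tb_fraction: float) -> Quantity:
    """Volumetric NOAEC in inhaled air from a critical alveolar volume rate.

    Chain: alveolar ventilation = (1 - dead space) x total ventilation;
    critical alveolar concentration = critical rate / alveolar ventilation;
    inhaled-air concentration = alveolar concentration x 1/(1 - head/TB).

    With 0.29 m^3/(day*kg), dead space 1/3, 0.069 ul/(day*kg) and head/TB 1/3
    the endpoint is 0.535 ul/m^3, printed as 0.54.
    """
    if ventilation_per_kg.canonical <= 0:
        raise ValueError("ventilation must be positive")
    if not 0 <= dead_space_fraction < 1:
        raise ValueError("dead-space fraction must lie in [0, 1)")
    if critical_alveolar_volume_rate.canonical < 0:
        raise ValueError("critical volume rate must be non-negative")
    alveolar_ventilation = ventilation_per_kg * (1.0 - dead_space_fraction)
    alveolar_conc = critical_alveolar_volume_rate / alveolar_ventilation
    inhaled = alveolar_conc * extrathoracic_correction(head_tb_fraction)
    return inhaled.to("ul/m^3")
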