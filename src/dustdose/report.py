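"""Sensitivity-grid execution and audit-style table rendering.

Bundles the nine-scenario sensitivity grid over the volumetric translation
(program version x deposition fractions x threshold x human half-time),
runs any list of scenarios deterministically, and renders results as CSV,
Markdown or JSON next to their printed reference values with per-cell
deviations after rounding.

Rounding policy: every computation is carried at full precision and rounded
half-up only at rendering, to the reference's printed decimals.  (Rounding
intermediates is a real failure mode: it turns the 6.93 grid cell into
6.97.)
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from . import deposition as dep
from .model_a import corrected_hec, density_division_audit
from .model_b import ModelBScenario, TranslationResult, hec_volumetric
from .physiology import load_physiology
from .quantities import Q

__all__ = [
    "GridResult",
    "round_half_up",
    "table4_scenarios",
    "TABLE4_PRINTED",
    "run_grid",
    "render",
    "reproduce_table",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (1.575 -> 1.58), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# the bundled nine-scenario sensitivity grid

#: printed reference cells for the sensitivity grid: one row per scenario,
#: (NOAEC, AF_lungburden, AF_clearance, HEC) in mg/m^3 / 1 / 1 / mg/m^3.
TABLE4_PRINTED = pd.DataFrame(
    [
        ["MPPD 2.0, IA off, OMB", 7.5, 16.4, 1.0, 400, 0.53, 0.93, 0.93, 0.53],
        ["MPPD 2.0, IA on, ONA", 6.3, 8.4, 1.0, 400, 0.63, 1.52, 0.93, 1.03],
        ["MPPD 2.11, ONA", 3.3, 8.8, 1.0, 400, 1.21, 0.76, 0.93, 0.98],
        ["MPPD 2.0, IA on, ONA", 6.3, 8.4, 4.2, 400, 2.66, 1.52, 0.93, 4.33],
        ["MPPD 2.11, ONA", 3.3, 8.8, 4.2, 400, 5.07, 0.76, 0.93, 4.14],
        ["MPPD 2.0, IA on, ONA", 6.3, 8.4, 1.0, 250, 0.63, 1.52, 0.58, 1.65],
        ["MPPD 2.11, ONA", 3.3, 8.8, 1.0, 250, 1.21, 0.76, 0.58, 1.58],
        ["MPPD 2.0, IA on, ONA", 6.3, 8.4, 4.2, 250, 2.66, 1.52, 0.58, 6.93],
        ["MPPD 2.11, ONA", 3.3, 8.8, 4.2, 250, 5.07, 0.76, 0.58, 6.62],
    ],
    columns=["scenario", "f_rat_pct", "f_human_pct", "threshold_ul_kg",
             "t_half_human_days", "noaec", "af_lungburden", "af_clearance",
             "hec"],
)

_RESULT_DECIMALS = {"noaec": 2, "af_lungburden": 2, "af_clearance": 2, "hec": 2}


def table4_scenarios() -> list[ModelBScenario]:
    """The nine bundled sensitivity scenarios, in printed row order."""
    rat = load_physiology("rat_reference_1kg")
    human_400 = load_physiology("human_MAK_Brown")
    scenarios = []
    for _, row in TABLE4_PRINTED.iterrows():
        human = dataclasses.replace(
            human_400, clearance_half_time=Q(row["t_half_human_days"], "day"))
        scenarios.append(ModelBScenario(
            rat=rat,
            human=human,
            rat_alveolar_fraction=row["f_rat_pct"] / 100,
            human_alveolar_fraction=row["f_human_pct"] / 100,
            threshold_volume_per_kg=Q(row["threshold_ul_kg"], "ul/kg"),
            particle_density=Q(1.0, "g/cm^3"),
            mppd_version_label=row["scenario"],
            label=row["scenario"],
        ))
    return scenarios


@dataclass(frozen=True)
class GridResult:
    """Ordered scenario results, optional printed reference and comparison."""

    rows: list  # (label, TranslationResult | Exception)
    reference: Optional[pd.DataFrame] = None
    comparison: Optional[pd.DataFrame] = None

    @property
    def max_abs_delta(self) -> float:
        if self.comparison is None or self.comparison.empty:
            return float("nan")
        return float(self.comparison["abs_delta"].max())

    def to_frame(self) -> pd.DataFrame:
        records = []
        for label, res in self.rows:
            if isinstance(res, Exception):
                records.append({"scenario": label, "error": str(res)})
                continue
            records.append({
                "scenario": label,
                "noaec": res.noaec_rat.magnitude_in("mg/m^3"),
                "af_lungburden": res.af_lungburden,
                "af_clearance": res.af_clearance,
                "hec": res.hec.magnitude_in("mg/m^3"),
                "dimension_audit_clean": res.dimension_audit_clean,
            })
        return pd.DataFrame(records)


def run_grid(scenarios: Sequence[ModelBScenario],
             reference: Optional[pd.DataFrame] = None) -> GridResult:
    """Run each scenario through the volumetric translation, order preserved.

    A failing scenario is recorded under its label without aborting the
    others.  When a printed reference is supplied, a per-cell comparison is
    built: computed values are rounded half-up to the reference decimals and
    the absolute deviation recorded (0 means exact agreement as printed).
    """
    if len(scenarios) == 0:
        raise ValueError("scenario list must be non-empty")
    rows = []
    for i, s in enumerate(scenarios):
        label = getattr(s, "label", "") or f"scenario {i + 1}"
        try:
            rows.append((label, hec_volumetric(s)))
        except Exception as exc:  # per-row containment
            rows.append((label, exc))
    comparison = None
    if reference is not None:
        records = []
        for (label, res), (_, ref) in zip(rows, reference.iterrows()):
            if isinstance(res, Exception):
                continue
            computed = {
                "noaec": res.noaec_rat.magnitude_in("mg/m^3"),
                "af_lungburden": res.af_lungburden,
                "af_clearance": res.af_clearance,
                "hec": res.hec.magnitude_in("mg/m^3"),
            }
            for col, dec in _RESULT_DECIMALS.items():
                if col not in ref:
                    continue
                rounded = round_half_up(computed[col], dec)
                records.append({
                    "scenario": label, "cell": col,
                    "computed": rounded, "printed": float(ref[col]),
                    "abs_delta": abs(rounded - float(ref[col])),
                })
        comparison = pd.DataFrame(records)
    return GridResult(rows=rows, reference=reference, comparison=comparison)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join(["---"] * len(cols)) + "|"]
    for _, row in df.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:g}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render(result: Union[GridResult, pd.DataFrame], format: str = "markdown",
           decimals: Optional[dict] = None) -> str:
    """Render a grid result (or plain frame) as csv, markdown or json.

    Numeric result columns are rounded half-up at the printed decimals
    (default 2); JSON keeps full precision so a render/parse round trip
    reproduces every magnitude exactly.
    """
    df = result.to_frame() if isinstance(result, GridResult) else result.copy()
    if format == "json":
        payload = df.to_dict(orient="records")
        if isinstance(result, GridResult) and result.comparison is not None:
            payload = {"rows": payload,
                       "comparison": result.comparison.to_dict(orient="records")}
        return json.dumps(payload, indent=2)
    dec = dict(_RESULT_DECIMALS)
    if decimals:
        dec.update(decimals)
    shown = df.copy()
    for col, d in dec.items():
        if col in shown.columns:
            shown[col] = shown[col].map(lambda x: round_half_up(x, d))
    if format == "csv":
        buf = io.StringIO()
        shown.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "markdown":
        return _markdown_table(shown)
    raise ValueError(f"unknown format {format!r}; use csv, markdown or json")


# ---------------------------------------------------------------------------
# one-command regeneration of the bundled tables


def _table1_frame() -> pd.DataFrame:
    table = dep.deposition_table()
    sweep = table[(table["substance"] == "toner_Muhle")
                  & (table["species"] == "rat")].copy()
    sweep = sweep.sort_values("density_g_cm3")
    return pd.DataFrame({
        "density_g_cm3": sweep["density_g_cm3"].values,
        "alveolar_fraction_pct": 100 * sweep["alveolar_fraction"].values,
    })


def _table3_frame() -> pd.DataFrame:
    vent = Q(0.29, "m^3/(day*kg)")
    dead_space = 1.0 / 3.0
    critical = Q(0.069, "ul/(day*kg)")
    head_tb = 1.0 / 3.0
    alveolar_vent = vent * (2.0 / 3.0)
    alveolar_conc = critical / alveolar_vent
    noaec = dep.first_derivation_chain(vent, dead_space, critical, head_tb)
    return pd.DataFrame([{
        "ventilation_m3_day_kg": vent.magnitude,
        "dead_space_fraction": dead_space,
        "alveolar_ventilation_m3_day_kg": alveolar_vent.magnitude_in("m^3/(day*kg)"),
        "critical_volume_ul_day_kg": critical.magnitude,
        "alveolar_concentration_ul_m3": alveolar_conc.magnitude_in("ul/m^3"),
        "head_tb_fraction": head_tb,
        "noaec_ul_m3": noaec.magnitude_in("ul/m^3"),
    }])


def _corrected_hec_frame() -> pd.DataFrame:
    rows = []
    for substance, hec_ref in (("toner", 0.134), ("TiO2", 1.07)):
        corrected = corrected_hec(Q(hec_ref, "mg/m^3"), 193, 349,
                                  Q(400, "day"), Q(255, "day"))
        rows.append({
            "substance": substance,
            "hec_reference_mg_m3": hec_ref,
            "surface_ratio_old": 193, "surface_ratio_new": 349,
            "t_half_old_days": 400, "t_half_new_days": 255,
            "hec_corrected_mg_m3": corrected.magnitude_in("mg/m^3"),
        })
    audit = density_division_audit(Q(1.06, "mg/m^3"), Q(4.3, "g/cm^3"))
    rows.append({
        "substance": "TiO2 density-division audit (1.06 / 4.3 g/cm^3)",
        "hec_reference_mg_m3": 1.06,
        "dimensionless_value": float(audit.honest_value),
        "dimension_ok": audit.dimension_ok,
    })
    return pd.DataFrame(rows)


def reproduce_table(which: str, format: str = "markdown") -> str:
    """Regenerate a bundled table: '1', '3', '4' or 'corrected-hec'."""
    which = str(which)
    if which == "1":
        return render(_table1_frame(), format,
                      decimals={"alveolar_fraction_pct": 1, "density_g_cm3": 1})
    if which == "3":
        return render(_table3_frame(), format,
                      decimals={c: 2 for c in _table3_frame().columns})
    if which == "4":
        grid = run_grid(table4_scenarios(), reference=TABLE4_PRINTED)
        return render(grid, format)
    if which == "corrected-hec":
        return render(_corrected_hec_frame(), format,
                      decimals={"hec_corrected_mg_m3": 2})
    raise ValueError(f"unknown table {which!r}; use 1, 3, 4 or corrected-hec")
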