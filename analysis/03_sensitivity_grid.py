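"""Run the nine-scenario volumetric sensitivity grid.

Varies the deposition-program version/settings (rat 7.5/6.3/3.3 %, human
16.4/8.4/8.8 %), the critical volume burden (1 vs 4.2 ul/kg) and the human
clearance half-time (400 vs 250 days), recomputes NOAEC, both adjustment
factors and the HEC for each scenario, and compares every cell against the
reference values.  Writes results/sensitivity_grid.csv and
results/sensitivity_grid_comparison.csv.
"""

from pathlib import Path

from dustdose.model_b import hec_simple_rule
from dustdose.quantities import Q
from dustdose.report import TABLE4_PRINTED, render, run_grid, table4_scenarios

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    grid = run_grid(table4_scenarios(), reference=TABLE4_PRINTED)

    (RESULTS / "sensitivity_grid.csv").write_text(render(grid, "csv"))
    grid.comparison.to_csv(RESULTS / "sensitivity_grid_comparison.csv",
                           index=False)

    print("Volumetric sensitivity grid (results/sensitivity_grid.csv):")
    print(render(grid, "markdown"))
    exact = int((grid.comparison["abs_delta"] == 0).sum())
    print(f"{exact}/36 cells agree exactly with the reference after rounding "
          f"(max |delta| = {grid.max_abs_delta}).")

    hecs = [r.hec.magnitude_in("mg/m^3") for _, r in grid.rows]
    rule = hec_simple_rule(Q(1, "g/cm^3")).magnitude_in("mg/m^3")
    print(f"\nHEC range across scenarios: {min(hecs):.2f}-{max(hecs):.2f} "
          f"mg/m^3 at density 1 g/cm^3, vs {rule:.1f} mg/m^3 from the "
          "published 0.5 x density shortcut — the corrected inputs raise "
          "every estimate, and the spread approaches an order of magnitude.")


if __name__ == "__main__":
    main()
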