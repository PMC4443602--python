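"""Reconstruct the volumetric (Model B) overload-threshold chain.

Derives the rat alveolar-macrophage pool volume from cell count and cell
volume, applies the 6 % Morrow overload criterion, renders it per gram of
lung (the reading whose unit was historically conflated with per-kg), and
walks the per-kg ventilation chain from the critical daily alveolar volume
to the volumetric NOAEC in inhaled air.  Writes results/table3_chain.csv.
"""

from pathlib import Path

from dustdose.deposition import extrathoracic_correction, first_derivation_chain
from dustdose.model_b import morrow_threshold, threshold_per_gram_lung
from dustdose.physiology import load_physiology, macrophage_pool_volume
from dustdose.quantities import Q
from dustdose.report import reproduce_table, round_half_up

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rat = load_physiology("rat_reference_1kg")

    pool = macrophage_pool_volume(rat.macrophage_count_per_kg,
                                  rat.macrophage_cell_volume)
    print(f"Rat macrophage pool: {rat.macrophage_count_per_kg:.0e}/kg x "
          f"{rat.macrophage_cell_volume.magnitude:.0f} um^3 = "
          f"{round_half_up(pool.magnitude_in('ul/kg'), 0):.0f} ul/kg")

    threshold = morrow_threshold(Q(70, "ul/kg"))
    print(f"Morrow 6% overload threshold: "
          f"{round_half_up(threshold.magnitude_in('ul/kg'), 1)} ul/kg")
    per_g = threshold_per_gram_lung(threshold, rat.lung_mass_per_kg)
    print(f"  per gram lung (4.5 g/kg): "
          f"{round_half_up(per_g.magnitude_in('ul/g'), 2)} ul/g "
          "(the 'about 1 ul/g' figure; using it per-kg understates the "
          "threshold 4.2-fold)")

    print(f"\nExtrathoracic corrections: head+TB 25% -> "
          f"{extrathoracic_correction(0.25):.3f}; head+TB 1/3 -> "
          f"{extrathoracic_correction(1/3):.2f}")

    noaec = first_derivation_chain(rat.ventilation_rate_per_kg,
                                   rat.dead_space_fraction,
                                   Q(0.069, "ul/(day*kg)"), 1 / 3)
    print(f"Volumetric NOAEC in inhaled air: "
          f"{round_half_up(noaec.magnitude_in('ul/m^3'), 2)} ul/m^3")

    (RESULTS / "table3_chain.csv").write_text(reproduce_table("3", "csv"))
    print("\nFull chain (results/table3_chain.csv):")
    print(reproduce_table("3", "markdown"))


if __name__ == "__main__":
    main()
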