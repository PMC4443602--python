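# Methods

## Scope and model structure

`dustdose` implements steady-state inhalation dosimetry for poorly soluble,
low-toxicity dusts and the two interspecies translation metrics used to
derive human equivalent concentrations (HECs) from rat overload NOAECs:
retained particle **mass per alveolar surface area** and retained particle
**volume per alveolar-macrophage pool volume**. Both sit on the same
one-compartment kinetic core:

* a single alveolar compartment with constant first-order clearance,
  dB/dt = D − kB, analytic solution B(t) = (D/k)(1 − e^(−kt));
* deposition rate D = C·F_a·V̇E (mass) or C·F_a·V̇E/ρ (volume), with the
  alveolar deposition fraction F_a taken from a bundled table of MPPD
  program outputs, never recomputed;
* steady state B_ss = D/k, and its inversion from a critical burden to a
  NOAEC.

Out of scope by design: the deposition physics itself (MPPD is treated as
an external program whose outputs are data), overload-dependent
(dose-varying) clearance, lymph-node translocation, particle dissolution,
and multi-compartment interstitial kinetics — the latter enters only
through shorter human half-times (250/255 days) used as parameters.

## The unit layer

Every model value is a `Quantity` holding a magnitude in a canonical
mg/m/day basis plus a signed exponent vector over (mass, length, time).
Base dimensions are deliberately restricted to those three: breaths and
cells are dimensionless counts, because daily ventilation volumes already
fold tidal volume × respiratory rate into m³/day. Compound units are parsed
from atomic ones (`g/cm^3`, `m^3/(day*kg)`, `um^3`); conversion between
same-dimension units is exact scaling, and round-trip conversion is
identity to 1e-12 relative (property-tested).

This layer is what makes the mass-per-surface density audit mechanical:
mg/m³ and g/cm³ have the *same* dimension (mass·length⁻³), so their
quotient is dimensionless. `assert_dimension` never raises — it returns a
pass/fail report naming both dimensions, and `density_division_audit`
carries the dimensionless value (2.465·10⁻¹⁰ for 1.06 mg/m³ ÷ 4.3 g/cm³)
to the report alongside the "unit-dropping" magnitude (0.25) that results
from dividing numbers and keeping the mg/m³ label. Both are reported
because both circulate.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| rat ventilation | 0.29 | m³/(day·kg) | 6 h × 60 min × 0.8 l/min per kg — encodes the exposure day; no extra 5/7 weekly factor (the grid reproduces exactly without one; a schedule hook would multiply V̇E) |
| human ventilation | 10 per 70 kg | m³/day | one working shift |
| dead-space fraction | 1/3 | – | of total inhaled volume |
| rat t½ | 60 | days | overload-free alveolar clearance, toner and TiO₂ alike |
| human t½ | 400 or 250/255 | days | 400 is the historical assumption; 255 from two-compartment alveolar–interstitial retention fits, ≈245 independently from quarter-power allometry |
| rat macrophage pool | 70 | µl/kg | 6·10⁷ cells/kg × 1166 µm³ |
| human macrophage pool | 500 | µl/kg | 50·10¹⁰ µm³ read per kg body weight — the only normalization under which AF_clearance = (t½_h/60)·(70/500) reproduces the reference grid cells 0.93 and 0.58 exactly |
| Morrow fraction | 6 % | – | classical overload-onset criterion |
| rat lung mass | 4.5 | g/kg | renders 4.2 µl/kg as 0.93 µl/g lung |
| alveolar surfaces | 0.2972/57.22 or 0.41/143 | m² | cast-based vs reference-method (ATS/ERS stereology) pairs; the registry carries all variants and the user selects |

Clearance rates are always ln2/t½ exactly. The rounded "0.01/day" for the
60-day rat half-time is *not* used: with it the first grid NOAEC would be
0.46 rather than the reproduced 0.53 mg/m³.

The volumetric threshold is normalized per kg body weight on both species.
The historical NOAEC equation mixed a per-g-lung threshold (≈1 µl/g) with
per-kg ventilation; both readings are representable here — 1 µl/kg and the
corrected 4.2 µl/kg are separate scenarios whose results differ by exactly
4.2. The equation's undocumented divisor (`fvi`) defaults to 1, the value
under which every tabulated output reproduces; it is exposed but not
guessed beyond that.

## Adjustment-factor closed forms

The published derivations cite but do not reprint the adjustment-factor
equations, so the implemented forms are reconstructions:
AF_lungburden = (V̇E_r F_r)/(V̇E_h F_h) and AF_clearance =
(t½_h/t½_r)·(pool_r/pool_h) are the unique split of the steady-state
burden-per-pool equivalence ratio that reproduces every tabulated AF and
HEC cell. `hec_volumetric` recomputes the full ratio
[V̇E_r F_r/(k_r·pool_r)] / [V̇E_h F_h/(k_h·pool_h)] independently on every
call and raises if the decomposition disagrees beyond 1e-10 relative — a
structural self-check, not a tolerance to tune. A useful corollary, also
property-tested: the rat deposition fraction cancels between the NOAEC and
AF_lungburden, so the HEC depends on F_r not at all.

Model A's result object uses the same decomposition with absolute
ventilations and AF_clearance = (k_r S_r)/(k_h S_h). Forward model-A runs
need an absolute rat ventilation, hence a rat body weight; the default
preset uses 0.25 kg with an override, since the historical choice is not
documented. Published forward HECs (0.133/1.02 family) are therefore kept
as labelled reference constants — the deposition settings behind them are
documented as irreproducible — and the correction path
(`corrected_hec` = HEC × (349/193) × (400/255)) operates on those
constants rather than pretending to re-derive them.

## Rounding and numerics

All computation is carried at full precision; rounding happens only at
rendering, half-up, to the reference table's printed decimals. Half-up
matters (banker's rounding flips 1.575 → 1.57) and so does the
no-rounded-intermediates rule (rounding the NOAEC and AFs first yields 6.97
instead of 6.93 in the highest-threshold grid row). Degenerate inputs fail
loudly: non-positive physiology, fractions outside [0,1), division by a
zero-magnitude quantity, unknown deposition keys (the table never
interpolates — version-to-version factor-2 differences are the point),
unsorted trajectory times.

## Synthetic data

The generator serves two purposes and emulates only what those require:

* **Scenario sampling** draws translation inputs uniformly from ranges
  bracketing the tabulated study conditions (F_a 3–20 %, rat t½ 30–120 d,
  human t½ 200–500 d, density 1–5 g/cm³, threshold 0.5–10 µl/kg), seeded
  per call with no global state, for metamorphic tests of the translation
  algebra.
* **Burden series** are the analytic trajectory times multiplicative
  lognormal noise, exp(σZ) with σ = 0.05 by default — burdens are positive
  and assay error scales with magnitude; the noise is median-unbiased so a
  log-scale least-squares fit is the matched estimator. Recovery uses
  `scipy.optimize.curve_fit` on (log D, log k) with residual-bootstrap
  intervals; series whose span does not reach one fitted half-time are
  flagged unidentifiable (only D is then constrained by the initial ramp).

What this does *not* emulate: real lung-burden data with
overload-progressive clearance impairment, inter-animal variability,
interstitial sequestration, or correlated longitudinal error. Passing
recovery tests show the estimator and forward model are mutually
consistent at realistic assay noise — not that a 60-day half-time is
recoverable from any particular in-vivo design.

Problem sizes used by the validation runs: 20 time points over 5–600 days
(ten half-times), 500 replicates for the bias summary; the observed
relative bias of the recovered clearance rate is ~0.2 %, comfortably inside
the 2 % design criterion.

## Known limitations

* Constant-clearance kinetics is exactly the assumption that overload
  violates; the models are therefore only meaningful *below* threshold.
* Deposition fractions are only as good as the bundled table; scenarios
  outside it require the user to supply their own rows, deliberately.
* The adjustment-factor closed forms are table-validated reconstructions;
  symbol-level agreement with the uncited original equations cannot be
  established from the sources in scope.
* The mass-per-surface forward mode reproduces a *method*, not the
  historical numbers, whose inputs are unrecoverable.
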