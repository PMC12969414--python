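# Methods

This note records the model implemented by `mr1scan`, the parameter choices
and their rationale, what the synthetic generator does and does not emulate,
and the known limitations. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Chemical model

A carbonyl ligand condenses with the ε-amine of the diagnostic peptide's
lysine (Schiff base, −H₂O) and is stabilized by reduction (+2H). The net
composition change is therefore the ligand formula minus one oxygen:

```
Δ-mass = M(ligand) − M(O) = M(ligand) − 15.9949146196 Da
M(ligand) = Δ-mass + M(O)        (reported as Delta_Mass_Oxygen)
```

The diagnostic peptide is **DSVTRQKEPRAPW** (neutral monoisotopic mass
1568.8059 Da), with the modifiable lysine at position 7 of 13. All masses are
monoisotopic, built from CODATA-consistent elemental masses and standard
amino-acid residue formulas; the proton mass used for m/z arithmetic is
1.007276466621 Da. `pyteomics` is used as an independent oracle in the tests
(mass and MGF round-trips), not as the implementation of the chemistry.

For an α-dicarbonyl such as glyoxal only one carbonyl reacts; the model makes
no distinction — the Δ-mass is always ligand − O, which for glyoxal
(C₂H₂O₂) gives 42.01 Da and for the positive controls pyridoxal (C₈H₉NO₃)
and pyridoxal 5′-phosphate 151.06 and 231.03 Da respectively.

Note on PLP: the Δ-mass derived from its formula is 231.0297 Da. A commonly
quoted rounded value is 231.01; the package derives all values from formulas
and never hard-codes rounded literals, so tests compare at the precision the
chemistry supports.

## Reporter-ion ladder and the open scan

For each MS/MS spectrum the screen:

1. Computes the neutral precursor mass from PEPMASS and charge and the
   candidate Δ-mass as (neutral − peptide mass). If the charge is absent,
   charges 2–4 are tried and the one maximizing matched reporters wins
   (ties → lowest charge).
2. Matches the 12 singly charged y-ions against the peak list by nearest
   peak within **15 ppm**. y1–y6 do not contain the lysine and sit at fixed
   m/z (anchoring peptide identity); y7–y12 contain it and are predicted at
   their unmodified m/z **plus Δ** (localizing the adduct). b-ions are
   computed by the library but not used as reporters: in this peptide they
   are complementary and add no independent site information, and y-ions
   dominate HCD spectra of tryptic-like peptides.
3. Applies the default filters: signed Δ ≥ **40 Da** (suppresses small
   artifactual shifts — deamidation, oxidation, isotope-selection errors)
   and ≥ **8** matched reporters to pass, ≥ **10** for the stringent tier.
   Closed-search (unmodified) spectra are those with |Δ| ≤ 10 ppm of the
   peptide mass.

The effective filter edges are not assumed: `scripts/acceptance.py` sweeps
noise-free synthetic spectra through the real scanner and confirms the
smallest passing Δ-mass is 40 Da, the smallest passing reporter count is 8,
and the smallest stringent count is 10.

## Error propagation

The ligand mass is obtained by subtracting a ~1.6 kDa constant from a
measured precursor, so the absolute precursor error lands on the ligand
nearly unchanged while the *relative* error balloons. For a precursor at
charge z with relative error p:

```
propagated_ppm(lig, p) = p × (M(peptide) + lig − M(O) + z·m_proton) / lig
```

Evaluated at z = 3 (worst typical case for this peptide). At 5 ppm precursor
accuracy a 40 Da ligand carries ≈ 200 ppm of inferred mass error, decaying
hyperbolically with ligand mass (≈ 52 ppm for pyridoxal, ≈ 15 ppm at 800 Da).
This motivates the two-stage annotation tolerance below. The absolute ±
window is nearly mass-independent (±0.008–0.012 Da at 5 ppm), because the
error lives on the precursor.

## Annotation

Recurring `Delta_Mass_Oxygen` values are matched against a compound table at
a **200 ppm** global tolerance — wide enough to keep true small ligands whose
propagated error is large. The ppm error is computed relative to the
*compound* mass. Hits are then filtered by the mass-dependent propagated
window at the instrument's precursor accuracy, so a 30 ppm hit on a 40 Da
compound survives (window ≈ 200 ppm) while the same 30 ppm on a 400 Da
compound is rejected (window ≈ 25 ppm).

Δ-masses are clustered across spectra by single-linkage with a **0.01 Da**
tolerance (matching the absolute window above) so repeated observations of
one adduct aggregate. Plausibility flags from the compound table (e.g.
`has_aldehyde`, `in_culture_medium`) can be required or excluded; a
compound missing a flag column is kept, not silently dropped. The shortlist
ranks by: not-excluded, stringent spectrum count, total spectrum count,
maximum reporter count, retention-time spread (adducts of one ligand
co-elute), then name for determinism.

## Calibration cutoff

Closed and open cumulative counts are computed over reporter thresholds
12 → 1. The closed curve plateaus once all clean unmodified spectra are in;
the open curve keeps growing as low-quality matches flood in. The suggested
cutoff is operationalized as: among steps where the open curve's relative
increase exceeds `ratio_threshold` (default 2.0) times the closed curve's
relative increase, take the step with the steepest open rise and return its
upper threshold. A step from zero to a positive count is treated as an
infinite relative rise; if both curves do so at the same step it is not a
qualifying step. If no step qualifies the minimum threshold is returned with
a warning. This reduces to "the threshold just above where the open search
explodes" on well-separated data while remaining defined on flat or noisy
curves.

## Synthetic generator

The generator produces ground-truthed MGF runs for validation and examples.
Per spectrum it emits the 12 reporter ions at their exact theoretical m/z
(shifted by the true Δ for site ions) at a fixed intensity of 1000, plus
uniform-m/z (200–2000), log-uniform-intensity (1–100) noise peaks, capped at
100 peaks total. Gaussian ppm error (default σ = 5) is applied to the
**precursor only**: fragment m/z are exact. This isolates the quantity under
study — Δ-mass recovery through precursor error — from fragment-matching
noise; fragment tolerance behaviour is tested separately with controlled
offsets. Unmodified spectra elute early, adducts late (hydrophobic shift),
decoys throughout; decoy precursors are redrawn until their implied Δ is at
least 1 Da from any panel Δ and from zero, so decoys can only match by
chance. Reporter policies `random-k` / `fixed-list` produce deliberately
degraded spectra for calibration studies.

What it does **not** emulate: isotope envelopes, chimeric spectra,
peak-intensity structure of real fragmentation, co-eluting interferences, or
charge-state misassignment.

## Problem sizes and numerical choices

- Δ-recovery validation uses 20,000 synthetic adduct spectra at 10 ppm
  precursor error and asserts ≥ 95 % of recovered Δ-masses fall within twice
  the propagated tolerance window (a 2σ criterion, true rate ≈ 95.4 %; the
  sample size keeps the test's false-failure probability below ~0.1 %).
  These sizes are the package's own validation choices.
- Fragment matching uses binary search (`np.searchsorted`) on sorted peak
  lists; occupancy ratios integrate chromatographic areas with
  `np.trapezoid`.
- All stochastic tests and the acceptance script take explicit seeds;
  hypothesis-based property tests are derandomized.

## Limitations

- Mass alone cannot distinguish isomers; the shortlist ranks candidates but
  cannot identify a unique structure. Orthogonal evidence (synthesis,
  retention time, MS/MS of the free compound) is required for confirmation.
- The screen assumes a single modification site on a single diagnostic
  peptide; multiply modified or missed-cleavage forms are out of scope.
- No isotope-envelope modelling: monoisotopic selection errors appear as
  ±1.003 Da Δ-mass artifacts and are only suppressed by the 40 Da floor.
- The calibration cutoff is heuristic and should be inspected against the
  plotted curves (`plot_curve`) rather than applied blindly.
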