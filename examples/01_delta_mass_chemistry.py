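"""The Schiff-base ligand ↔ Δ-mass conversion and the reporter-ion ladder.

A carbonyl metabolite that condenses with the ε-amine of the diagnostic
peptide's lysine and is then reduced leaves the peptide heavier by the
ligand mass minus one oxygen. This script prints the expected Δ-masses
of the two vitamin-B6 controls and of glyoxal, and the y-ion ladder the
scanner matches against.
"""

from mr1scan import (
    DiagnosticPeptide,
    delta_from_ligand_mass,
    fragment_ladder,
    parse_formula,
    peptide_neutral_mass,
)

peptide = DiagnosticPeptide()
print(f"diagnostic peptide {peptide.sequence}, modifiable K at position {peptide.site_index}")
print(f"neutral monoisotopic mass: {peptide.neutral_mass:.4f} Da\n")

for name, formula in [
    ("pyridoxal", "C8H9NO3"),
    ("pyridoxal 5'-phosphate", "C8H10NO6P"),
    ("glyoxal", "C2H2O2"),
]:
    mass = parse_formula(formula)
    delta = delta_from_ligand_mass(mass)
    print(f"{name:24s} {formula:10s} ligand {mass:9.4f} Da -> Δ-mass {delta:9.4f} Da")

print("\ny-ion ladder (singly charged); site-containing ions shift by Δ on the adduct:")
for ion in fragment_ladder(peptide, ("y",), 1):
    tag = "shifts with Δ" if ion.contains_site else "fixed"
    print(f"  {ion.label:4s} m/z {ion.mz_unmodified:10.4f}  ({tag})")

# The Δ-mass values are what the scanner reads off precursor masses; the
# fixed y1–y6 anchor the peptide identity while shifted y7–y12 localize
# the adduct to the lysine.
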