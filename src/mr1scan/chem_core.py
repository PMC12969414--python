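"""Monoisotopic mass chemistry for the MR1 Δ-mass screen.

Everything downstream of this module reasons about neutral monoisotopic
masses: elemental formulas for candidate ligands, the diagnostic MR1
peptide DSVTRQKEPRAPW and its b/y fragment-ion ladder, and the
Schiff-base ligand ↔ Δ-mass conversion.

The chemistry behind the conversion: an aldehyde/ketone ligand condenses
with the ε-amine of the peptide's lysine to a Schiff base (losing H2O),
which reductive amination then reduces to a stable secondary amine
(adding 2 H). Net mass change of the peptide relative to peptide +
free ligand is therefore −O: the observed precursor Δ-mass equals the
free-ligand monoisotopic mass minus one oxygen.

Average masses are not supported; all arithmetic is monoisotopic, and
m/z uses the proton-adduct convention without electron-mass correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "OXYGEN_MASS",
    "WATER_MASS",
    "ELEMENT_MASSES",
    "RESIDUE_MASSES",
    "DEFAULT_PEPTIDE_SEQUENCE",
    "DEFAULT_SITE_INDEX",
    "DiagnosticPeptide",
    "FragmentIon",
    "FormulaError",
    "SequenceError",
    "parse_formula",
    "peptide_neutral_mass",
    "fragment_ladder",
    "ligand_mass_from_delta",
    "delta_from_ligand_mass",
    "neutral_from_mz",
    "mz_from_neutral",
]

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.007276466621

#: Monoisotopic element masses (Da), IUPAC/CODATA values.
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
}

HYDROGEN_MASS = ELEMENT_MASSES["H"]
OXYGEN_MASS = ELEMENT_MASSES["O"]
WATER_MASS = 2.0 * HYDROGEN_MASS + OXYGEN_MASS

# Residue elemental compositions (the residue = amino acid − H2O).
_RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

DEFAULT_PEPTIDE_SEQUENCE = "DSVTRQKEPRAPW"
#: 1-based position of the modifiable lysine (K43 in MR1 coordinates).
DEFAULT_SITE_INDEX = 7


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


class SequenceError(ValueError):
    """Raised for peptide sequences containing non-canonical letters."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of an elemental formula.

    Accepts element symbols with optional integer counts, e.g.
    ``"C8H9NO3"`` (pyridoxal) → 167.0582 Da.

    Raises
    ------
    FormulaError
        If the formula is empty, contains an unknown element symbol,
        or has text that does not tokenize as element/count pairs.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    mass = 0.0
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r} at {formula[pos:]!r}"
            )
        symbol, count_text = m.group(1), m.group(2)
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element {symbol!r} in {formula!r}")
        count = int(count_text) if count_text else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {formula!r}")
        mass += ELEMENT_MASSES[symbol] * count
        pos = m.end()
    return mass


#: Monoisotopic residue masses for the 20 canonical amino acids, Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: parse_formula(f) for aa, f in _RESIDUE_FORMULAS.items()
}


def peptide_neutral_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide: Σ residues + H2O.

    Raises
    ------
    SequenceError
        If the sequence is empty or contains a non-canonical letter.
    """
    if not sequence:
        raise SequenceError("empty peptide sequence")
    mass = WATER_MASS
    for letter in sequence:
        try:
            mass += RESIDUE_MASSES[letter]
        except KeyError:
            raise SequenceError(
                f"non-canonical residue {letter!r} in {sequence!r}"
            ) from None
    return mass


@dataclass(frozen=True)
class DiagnosticPeptide:
    """The fixed peptide backbone of the Δ-mass screen.

    Parameters
    ----------
    sequence
        Canonical residue letters. Defaults to the chymotryptic MR1
        peptide DSVTRQKEPRAPW carrying K43.
    site_index
        1-based position of the single modifiable residue (the lysine
        whose ε-amine carries the ligand adduct). Defaults to 7.
    """

    sequence: str = DEFAULT_PEPTIDE_SEQUENCE
    site_index: int = DEFAULT_SITE_INDEX

    def __post_init__(self) -> None:
        peptide_neutral_mass(self.sequence)  # validates letters / emptiness
        if not 1 <= self.site_index <= len(self.sequence):
            raise ValueError(
                f"site_index {self.site_index} outside 1..{len(self.sequence)}"
            )

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass of the unmodified peptide, Da."""
        return peptide_neutral_mass(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical b- or y-ion of the diagnostic peptide.

    ``contains_site`` marks ions that include the modifiable lysine and
    therefore shift by Δ on the modified peptide; site-free ions sit at
    their canonical m/z regardless of the adduct.
    """

    series: str
    ordinal: int
    charge: int
    contains_site: bool
    mz_unmodified: float

    @property
    def label(self) -> str:
        if self.charge == 1:
            return f"{self.series}{self.ordinal}"
        return f"{self.series}{self.ordinal}^{self.charge}+"


def fragment_ladder(
    peptide: DiagnosticPeptide,
    series_set: Iterable[str] = ("y",),
    max_fragment_charge: int = 1,
) -> list[FragmentIon]:
    """All b/y fragment ions of the peptide, ordinals 1..len−1.

    b_k covers the first k residues (m/z = Σ residues + z·proton over z);
    y_k covers the last k residues (m/z = Σ residues + H2O + z·proton
    over z). Each ion is annotated with whether it contains the
    modifiable site.
    """
    series_set = set(series_set)
    unknown = series_set - {"b", "y"}
    if unknown:
        raise ValueError(f"unsupported fragment series: {sorted(unknown)}")
    if max_fragment_charge < 1:
        raise ValueError("max_fragment_charge must be ≥ 1")

    n = len(peptide.sequence)
    residues = [RESIDUE_MASSES[a] for a in peptide.sequence]
    ions: list[FragmentIon] = []
    for series in sorted(series_set):
        for k in range(1, n):
            if series == "b":
                neutral = sum(residues[:k])
                contains_site = peptide.site_index <= k
            else:
                neutral = sum(residues[n - k:]) + WATER_MASS
                contains_site = peptide.site_index > n - k
            for z in range(1, max_fragment_charge + 1):
                ions.append(
                    FragmentIon(
                        series=series,
                        ordinal=k,
                        charge=z,
                        contains_site=contains_site,
                        mz_unmodified=(neutral + z * PROTON_MASS) / z,
                    )
                )
    return ions


def ligand_mass_from_delta(delta_mass: float) -> float:
    """Free-ligand neutral mass from an observed precursor Δ-mass.

    The reduced Schiff-base adduct carries the ligand minus one oxygen
    (condensation loses H2O, reduction restores 2 H), so the free
    ligand mass is Δ + O. This is the quantity reported downstream as
    ``Delta_Mass_Oxygen``.
    """
    return delta_mass + OXYGEN_MASS


def delta_from_ligand_mass(ligand_mass: float) -> float:
    """Expected precursor Δ-mass for a given free-ligand mass.

    Exact inverse of :func:`ligand_mass_from_delta`.

    Raises
    ------
    ValueError
        If the ligand mass does not exceed one oxygen (no such
        carbonyl ligand can exist).
    """
    if ligand_mass <= OXYGEN_MASS:
        raise ValueError(
            f"ligand mass {ligand_mass} Da must exceed {OXYGEN_MASS:.4f} Da"
        )
    return ligand_mass - OXYGEN_MASS


def neutral_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from m/z under the proton-adduct convention."""
    if charge < 1:
        raise ValueError("charge must be ≥ 1")
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return charge * mz - charge * PROTON_MASS


def mz_from_neutral(mass: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError("charge must be ≥ 1")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (mass + charge * PROTON_MASS) / charge
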