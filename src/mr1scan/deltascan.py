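"""The open Δ-mass screen against the diagnostic MR1 peptide.

For every MS/MS spectrum the scanner computes the precursor Δ-mass
relative to unmodified DSVTRQKEPRAPW, matches the sequence-specific
reporter-ion ladder (site-free y-ions at canonical m/z, site-containing
y-ions shifted by Δ), counts matched reporters, infers the free-ligand
mass, and applies the default filters (Δ ≥ 40 Da, ≥8 reporters). The
table it emits mirrors the protocol's LigandScannerAbsolute.csv layout,
including the "#Fragments" and "Delta_Mass_Oxygen" column labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    OXYGEN_MASS,
    DiagnosticPeptide,
    FragmentIon,
    fragment_ladder,
    ligand_mass_from_delta,
    neutral_from_mz,
)
from .mgf_io import MsmsSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "DeltaMassRecord",
    "compute_delta",
    "match_reporters",
    "scan",
    "records_to_frame",
    "stringent_filter",
    "occupancy_ratio",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scanner parameters; the defaults encode the protocol's settings.

    min_mass_shift
        Smallest Δ-mass (Da) flagged as a candidate adduct. Default 40:
        MR1 rarely binds ligands below that size (glyoxal, the smallest
        validated case, shifts by 42 Da).
    min_frag_number
        Minimum matched reporter ions for a record to pass. Default 8.
    fragment_tol_ppm
        Fragment-matching tolerance; 15 ppm suits Orbitrap MS2 at
        60,000 resolution.
    candidate_precursor_charges
        Charges tried when the file states none (DDA selection range).
    reporter_series / reporter_fragment_charges
        The reporter ladder; default singly charged y-ions (12 ions for
        the 13-residue peptide).
    stringent_y_min
        y-ion count for the stringent mode used alongside PSM-level FDR
        control. Default 10.
    closed_search_epsilon_ppm
        |Δ| window (ppm of the peptide mass) defining the closed search.
    """

    min_mass_shift: float = 40.0
    min_frag_number: int = 8
    fragment_tol_ppm: float = 15.0
    candidate_precursor_charges: tuple[int, ...] = (2, 3, 4)
    reporter_series: tuple[str, ...] = ("y",)
    reporter_fragment_charges: tuple[int, ...] = (1,)
    stringent_y_min: int = 10
    closed_search_epsilon_ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.min_mass_shift < 0 or self.min_frag_number < 0:
            raise ValueError("thresholds must be non-negative")
        if self.fragment_tol_ppm <= 0 or self.closed_search_epsilon_ppm <= 0:
            raise ValueError("tolerances must be positive")

    def ladder(self, peptide: DiagnosticPeptide) -> list[FragmentIon]:
        return fragment_ladder(
            peptide,
            series_set=self.reporter_series,
            max_fragment_charge=max(self.reporter_fragment_charges),
        )


@dataclass
class DeltaMassRecord:
    """One scanner output row per spectrum."""

    spectrum_ordinal: int
    scan_title: str
    retention_time: float | None
    precursor_mz: float
    assumed_charge: int
    delta_mass: float
    reporter_flags: dict[str, bool]
    n_fragments: int
    delta_mass_oxygen: float
    passes_filters: bool
    stringent: bool | None = None

    @property
    def n_y_ions(self) -> int:
        return sum(v for k, v in self.reporter_flags.items() if k.startswith("y"))


def _reporter_ions(peptide: DiagnosticPeptide, config: ScanConfig) -> list[FragmentIon]:
    ions = config.ladder(peptide)
    wanted = set(config.reporter_fragment_charges)
    return [ion for ion in ions if ion.charge in wanted]


def match_reporters(
    spectrum: MsmsSpectrum,
    peptide: DiagnosticPeptide,
    delta_mass: float,
    config: ScanConfig = ScanConfig(),
) -> tuple[dict[str, bool], int]:
    """Flag each reporter ion present in the spectrum.

    Site-free ions are sought at their canonical m/z; site-containing
    ions at m/z + Δ/z. An ion matches when the nearest peak lies within
    ``fragment_tol_ppm``; each theoretical ion claims at most that one
    nearest peak. Returns the per-ion flags and the matched count
    ("#Fragments").
    """
    ions = _reporter_ions(peptide, config)
    flags: dict[str, bool] = {}
    mz = spectrum.mz
    for ion in ions:
        expected = ion.mz_unmodified
        if ion.contains_site:
            expected = ion.mz_unmodified + delta_mass / ion.charge
        matched = False
        if mz.size and expected > 0:
            idx = int(np.searchsorted(mz, expected))
            best = min(
                (i for i in (idx - 1, idx) if 0 <= i < mz.size),
                key=lambda i: abs(mz[i] - expected),
            )
            ppm = abs(mz[best] - expected) / expected * 1e6
            matched = bool(ppm <= config.fragment_tol_ppm)
        flags[ion.label] = matched
    return flags, sum(flags.values())


def compute_delta(
    spectrum: MsmsSpectrum,
    peptide: DiagnosticPeptide,
    config: ScanConfig = ScanConfig(),
) -> tuple[int, float]:
    """Assumed charge and precursor Δ-mass for one spectrum.

    With a known charge, Δ = neutral(precursor) − peptide mass (may be
    negative). With unknown charge every candidate charge is evaluated
    and the one maximizing the matched reporter count wins (tie →
    lowest charge).
    """
    pep_mass = peptide.neutral_mass
    if spectrum.precursor_charge is not None:
        z = spectrum.precursor_charge
        return z, neutral_from_mz(spectrum.precursor_mz, z) - pep_mass

    best: tuple[int, int, float] | None = None  # (-n_frag, charge, delta)
    for z in sorted(config.candidate_precursor_charges):
        delta = neutral_from_mz(spectrum.precursor_mz, z) - pep_mass
        _, n_frag = match_reporters(spectrum, peptide, delta, config)
        key = (-n_frag, z, delta)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1], best[2]


def _build_record(
    spectrum: MsmsSpectrum,
    peptide: DiagnosticPeptide,
    config: ScanConfig,
) -> DeltaMassRecord:
    charge, delta = compute_delta(spectrum, peptide, config)
    flags, n_frag = match_reporters(spectrum, peptide, delta, config)
    return DeltaMassRecord(
        spectrum_ordinal=spectrum.ordinal,
        scan_title=spectrum.scan_title,
        retention_time=spectrum.retention_time,
        precursor_mz=spectrum.precursor_mz,
        assumed_charge=charge,
        delta_mass=delta,
        reporter_flags=flags,
        n_fragments=n_frag,
        delta_mass_oxygen=ligand_mass_from_delta(delta),
        passes_filters=(delta >= config.min_mass_shift)
        and (n_frag >= config.min_frag_number),
    )


def scan(
    spectra: Iterable[MsmsSpectrum],
    peptide: DiagnosticPeptide = DiagnosticPeptide(),
    config: ScanConfig = ScanConfig(),
    out_csv: str | None = None,
) -> list[DeltaMassRecord]:
    """Run the Δ-mass screen: one record per spectrum, in input order.

    No spectrum is dropped — records failing the filters are retained
    with ``passes_filters`` False so QC on negative Δ and low counts
    stays possible. When ``out_csv`` is given, the table is written in
    the LigandScannerAbsolute.csv layout.
    """
    records = [_build_record(s, peptide, config) for s in spectra]
    n_pass = sum(r.passes_filters for r in records)
    if records:
        deltas = [r.delta_mass for r in records]
        logger.info(
            "scanned %d spectra: %d passing (Δ ≥ %.0f Da, ≥%d reporters); Δ range %.3f..%.3f Da",
            len(records), n_pass, config.min_mass_shift,
            config.min_frag_number, min(deltas), max(deltas),
        )
    else:
        logger.info("scanned 0 spectra")
    if out_csv is not None:
        records_to_frame(records).to_csv(out_csv, index=False, encoding="utf-8")
    return records


def records_to_frame(records: Sequence[DeltaMassRecord]) -> pd.DataFrame:
    """Scanner records as a DataFrame with the protocol's column labels."""
    flag_labels: list[str] = []
    if records:
        flag_labels = list(records[0].reporter_flags.keys())
    rows = []
    for r in records:
        row = {
            "spectrum_ordinal": r.spectrum_ordinal,
            "scan_title": r.scan_title,
            "rt_seconds": r.retention_time if r.retention_time is not None else np.nan,
            "precursor_mz": r.precursor_mz,
            "assumed_charge": r.assumed_charge,
            "Delta_Mass": r.delta_mass,
        }
        for label in flag_labels:
            row[label] = int(r.reporter_flags.get(label, False))
        row["#Fragments"] = r.n_fragments
        row["Delta_Mass_Oxygen"] = r.delta_mass_oxygen
        row["passes_filters"] = int(r.passes_filters)
        if r.stringent is not None:
            row["stringent"] = int(r.stringent)
        rows.append(row)
    columns = (
        ["spectrum_ordinal", "scan_title", "rt_seconds", "precursor_mz",
         "assumed_charge", "Delta_Mass"]
        + flag_labels
        + ["#Fragments", "Delta_Mass_Oxygen", "passes_filters"]
        + (["stringent"] if records and records[0].stringent is not None else [])
    )
    return pd.DataFrame(rows, columns=columns)


def stringent_filter(
    records: Sequence[DeltaMassRecord],
    config: ScanConfig = ScanConfig(),
) -> list[DeltaMassRecord]:
    """Annotate records with the stringent mode flag (≥10 matched y-ions).

    The stricter threshold corresponds to the plateau region of the
    closed-search calibration and is recommended alongside PSM-level
    FDR control. Returns new records; the input is not mutated.
    """
    return [
        replace(r, stringent=r.n_y_ions >= config.stringent_y_min) for r in records
    ]


def occupancy_ratio(
    trace_modified: Sequence[tuple[float, float]],
    trace_unmodified: Sequence[tuple[float, float]],
) -> float:
    """Ratio of XIC areas: ligand-modified over unmodified peptide.

    Trapezoidal integration of each (time, intensity) trace. The ratio
    is a *relative* occupancy estimate only — ionization efficiency can
    differ between the modified and unmodified species, so it must not
    be read as an absolute ligand abundance.

    Raises
    ------
    ValueError
        On traces with fewer than two points, non-increasing times, or
        zero unmodified area.
    """
    def _area(trace: Sequence[tuple[float, float]], name: str) -> float:
        t = np.asarray([p[0] for p in trace], dtype=float)
        y = np.asarray([p[1] for p in trace], dtype=float)
        if t.size < 2:
            raise ValueError(f"{name} trace needs ≥2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{name} trace times must be strictly increasing")
        return float(np.trapezoid(y, t))

    area_mod = _area(trace_modified, "modified")
    area_unmod = _area(trace_unmodified, "unmodified")
    if area_unmod == 0:
        raise ValueError("unmodified trace has zero area; ratio undefined")
    return area_mod / area_unmod
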