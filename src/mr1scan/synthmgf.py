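"""Synthetic DDA-like MGF generator with known ground truth.

Emulates what the Δ-mass screen sees after conversion of a raw DDA run:
centroided MS/MS spectra of the ligand-modified and unmodified
diagnostic peptide plus decoy scans of unrelated precursors. Every
spectrum has a ground-truth row, so scanner recovery, false-positive
behaviour and threshold calibration can all be tested without any
external data.

What it emulates — precursor selection at charges 2–3, Gaussian ppm
precursor mass error, implanted singly charged y reporter ions (site
ions shifted by the true Δ), uniform-random noise peaks over the
acquisition m/z range, a top-N intensity cap, and later elution of the
more hydrophobic modified peptide. What it does not — isotope
envelopes, co-isolation/chimeric spectra, intensity response models, or
retention-time prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    OXYGEN_MASS,
    PROTON_MASS,
    DiagnosticPeptide,
    delta_from_ligand_mass,
    fragment_ladder,
    mz_from_neutral,
    parse_formula,
)
from .mgf_io import MsmsSpectrum

__all__ = ["LigandSpec", "SyntheticConfig", "generate", "worked_example_fixture"]

REPORTER_INTENSITY = 1000.0
NOISE_MZ_RANGE = (200.0, 2000.0)  # acquisition scan range
NOISE_INTENSITY_RANGE = (1.0, 100.0)  # log-uniform, below reporter intensity
DECOY_PRECURSOR_MZ_RANGE = (400.0, 1200.0)


@dataclass(frozen=True)
class LigandSpec:
    """One panel entry: a ligand and how many adduct spectra to emit."""

    name: str
    formula: str | None = None
    monoisotopic_mass: float | None = None
    n_spectra: int = 10

    def mass(self) -> float:
        if self.monoisotopic_mass is not None:
            return self.monoisotopic_mass
        if self.formula is None:
            raise ValueError(f"ligand {self.name!r} needs a formula or a mass")
        return parse_formula(self.formula)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the screen's study conditions.

    ``reporter_policy`` controls which of the 12 y-ions each adduct or
    unmodified spectrum carries: "all", "random-k" (uniform count in
    ``reporter_k_range``), or "fixed-list" (labels in
    ``reporter_fixed``). Mass error is Gaussian on the precursor m/z
    with ``mass_error_ppm_sd`` ppm; fragment peaks are exact. The seed
    is mandatory — all randomness flows from it.
    """

    peptide: DiagnosticPeptide = DiagnosticPeptide()
    ligand_panel: tuple[LigandSpec, ...] = (
        LigandSpec("pyridoxal", formula="C8H9NO3", n_spectra=10),
        LigandSpec("pyridoxal 5'-phosphate", formula="C8H10NO6P", n_spectra=10),
    )
    n_unmodified_spectra: int = 10
    n_decoy_spectra: int = 20
    reporter_policy: str = "all"
    reporter_k_range: tuple[int, int] = (8, 12)
    reporter_fixed: tuple[str, ...] = ()
    mass_error_ppm_sd: float = 5.0
    n_noise_peaks_per_spectrum: int = 30
    precursor_charges: tuple[int, ...] = (2, 3)
    rt_range: tuple[float, float] = (1200.0, 3000.0)
    peak_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_cap < 1:
            raise ValueError("peak_cap must be ≥ 1")
        if self.reporter_policy not in {"all", "random-k", "fixed-list"}:
            raise ValueError(f"unknown reporter policy {self.reporter_policy!r}")
        if self.mass_error_ppm_sd < 0 or self.n_noise_peaks_per_spectrum < 0:
            raise ValueError("noise settings must be non-negative")


def _pick_reporters(
    ions: Sequence, config: SyntheticConfig, rng: np.random.Generator
) -> list:
    if config.reporter_policy == "all":
        return list(ions)
    if config.reporter_policy == "fixed-list":
        wanted = set(config.reporter_fixed)
        return [ion for ion in ions if ion.label in wanted]
    lo, hi = config.reporter_k_range
    k = int(rng.integers(lo, hi + 1))
    k = min(k, len(ions))
    idx = rng.choice(len(ions), size=k, replace=False)
    return [ions[i] for i in sorted(idx)]


def _assemble_peaks(
    reporter_mz: Sequence[float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    mz = list(reporter_mz)
    inten = [REPORTER_INTENSITY] * len(mz)
    n_noise = config.n_noise_peaks_per_spectrum
    if n_noise:
        lo, hi = NOISE_MZ_RANGE
        mz.extend(rng.uniform(lo, hi, size=n_noise))
        ilo, ihi = NOISE_INTENSITY_RANGE
        inten.extend(np.exp(rng.uniform(np.log(ilo), np.log(ihi), size=n_noise)))
    mz_arr = np.asarray(mz)
    inten_arr = np.asarray(inten)
    if mz_arr.size > config.peak_cap:  # keep the most intense, as the converter would
        keep = np.argsort(inten_arr)[::-1][: config.peak_cap]
        mz_arr, inten_arr = mz_arr[keep], inten_arr[keep]
    order = np.argsort(mz_arr)
    return mz_arr[order], inten_arr[order]


def _peptide_spectrum(
    delta: float,
    label: str,
    ordinal: int,
    rt: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[MsmsSpectrum, list[str]]:
    ions = fragment_ladder(config.peptide, series_set=("y",), max_fragment_charge=1)
    implanted = _pick_reporters(ions, config, rng)
    frag_mz = [
        ion.mz_unmodified + (delta / ion.charge if ion.contains_site else 0.0)
        for ion in implanted
    ]
    z = int(rng.choice(config.precursor_charges))
    true_mz = mz_from_neutral(config.peptide.neutral_mass + delta, z)
    observed_mz = true_mz * (1.0 + rng.normal(0.0, config.mass_error_ppm_sd) * 1e-6)
    mz, inten = _assemble_peaks(frag_mz, config, rng)
    spec = MsmsSpectrum(
        scan_title=label,
        precursor_mz=observed_mz,
        precursor_charge=z,
        retention_time=rt,
        mz=mz,
        intensity=inten,
        ordinal=ordinal,
    )
    return spec, [ion.label for ion in implanted]


def generate(config: SyntheticConfig) -> tuple[list[MsmsSpectrum], pd.DataFrame]:
    """Generate spectra and their ground-truth table.

    Order: adduct spectra per panel entry, unmodified spectra, decoys.
    Adduct retention times sit later in the run than unmodified ones
    (ligand cross-linking increases hydrophobicity); decoys span the
    whole range. Decoy precursors are redrawn until their implied Δ at
    the assigned charge avoids ±1 Da of every panel Δ, so ground truth
    stays unambiguous.
    """
    rng = np.random.default_rng(config.seed)
    rt_lo, rt_hi = config.rt_range
    span = rt_hi - rt_lo
    spectra: list[MsmsSpectrum] = []
    truth_rows: list[dict] = []

    panel_deltas = [delta_from_ligand_mass(lig.mass()) for lig in config.ligand_panel]

    for lig, delta in zip(config.ligand_panel, panel_deltas):
        for i in range(lig.n_spectra):
            rt = float(rng.uniform(rt_lo + 0.3 * span, rt_hi))
            spec, implanted = _peptide_spectrum(
                delta, f"adduct:{lig.name}:{i}", len(spectra), rt, config, rng
            )
            spectra.append(spec)
            truth_rows.append(
                {
                    "spectrum_ordinal": spec.ordinal,
                    "truth_class": "adduct",
                    "ligand": lig.name,
                    "true_delta_mass": delta,
                    "implanted_reporters": ";".join(implanted),
                    "n_implanted_reporters": len(implanted),
                    "true_charge": spec.precursor_charge,
                    "rt": rt,
                }
            )

    for i in range(config.n_unmodified_spectra):
        rt = float(rng.uniform(rt_lo, rt_lo + 0.4 * span))
        spec, implanted = _peptide_spectrum(
            0.0, f"unmodified:{i}", len(spectra), rt, config, rng
        )
        spectra.append(spec)
        truth_rows.append(
            {
                "spectrum_ordinal": spec.ordinal,
                "truth_class": "unmodified",
                "ligand": "",
                "true_delta_mass": 0.0,
                "implanted_reporters": ";".join(implanted),
                "n_implanted_reporters": len(implanted),
                "true_charge": spec.precursor_charge,
                "rt": rt,
            }
        )

    pep_mass = config.peptide.neutral_mass
    for i in range(config.n_decoy_spectra):
        z = int(rng.choice(config.precursor_charges))
        while True:
            pre_mz = float(rng.uniform(*DECOY_PRECURSOR_MZ_RANGE))
            implied_delta = z * pre_mz - z * PROTON_MASS - pep_mass
            if all(abs(implied_delta - d) > 1.0 for d in panel_deltas + [0.0]):
                break
        mz, inten = _assemble_peaks([], config, rng)
        rt = float(rng.uniform(rt_lo, rt_hi))
        spec = MsmsSpectrum(
            scan_title=f"decoy:{i}",
            precursor_mz=pre_mz,
            precursor_charge=z,
            retention_time=rt,
            mz=mz,
            intensity=inten,
            ordinal=len(spectra),
        )
        spectra.append(spec)
        truth_rows.append(
            {
                "spectrum_ordinal": spec.ordinal,
                "truth_class": "decoy",
                "ligand": "",
                "true_delta_mass": implied_delta,
                "implanted_reporters": "",
                "n_implanted_reporters": 0,
                "true_charge": z,
                "rt": rt,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "spectrum_ordinal", "truth_class", "ligand", "true_delta_mass",
            "implanted_reporters", "n_implanted_reporters", "true_charge", "rt",
        ],
    )
    return spectra, truth


def worked_example_fixture() -> tuple[list[MsmsSpectrum], pd.DataFrame]:
    """Deterministic noise-free 6-spectrum regression fixture.

    2 pyridoxal adducts, 1 glyoxal adduct, 1 unmodified peptide and 2
    decoys — small enough to eyeball, rich enough to exercise every
    scanner branch (passing adducts, Δ≈0 below the mass-shift floor,
    decoys with no reporters).
    """
    config = SyntheticConfig(
        ligand_panel=(
            LigandSpec("pyridoxal", formula="C8H9NO3", n_spectra=2),
            LigandSpec("glyoxal", formula="C2H2O2", n_spectra=1),
        ),
        n_unmodified_spectra=1,
        n_decoy_spectra=2,
        mass_error_ppm_sd=0.0,
        n_noise_peaks_per_spectrum=0,
        precursor_charges=(3,),
        seed=20230614,
    )
    return generate(config)
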