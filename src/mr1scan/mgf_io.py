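"""Reading and writing centroided MS/MS peak lists in Mascot Generic Format.

The screen consumes .mgf files as produced by MSConvert with vendor peak
picking and a top-100 intensity filter; this module does not re-filter
peaks — it preserves whatever the converter wrote. Parsing is delegated
to :mod:`pyteomics.mgf`; writing uses a plain formatter so round trips
are lossless to ≥6 significant digits.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence, Union

import numpy as np
from pyteomics import mgf as _pyteomics_mgf

logger = logging.getLogger(__name__)

__all__ = ["MsmsSpectrum", "MgfParseError", "read_mgf", "write_mgf", "rt_window_filter"]


class MgfParseError(ValueError):
    """Raised when an MGF block cannot be parsed."""


@dataclass
class MsmsSpectrum:
    """One centroided MS/MS scan.

    Attributes
    ----------
    scan_title
        TITLE line text (may be empty; duplicates allowed).
    precursor_mz
        Precursor m/z (Th), from PEPMASS.
    precursor_charge
        Assumed precursor charge, or ``None`` when the file does not
        state one.
    retention_time
        Seconds (RTINSECONDS), or ``None`` when absent.
    mz, intensity
        Parallel peak arrays, sorted by ascending m/z.
    ordinal
        File-order index (0-based); the stable spectrum identifier.
    """

    scan_title: str
    precursor_mz: float
    precursor_charge: int | None = None
    retention_time: float | None = None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    ordinal: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.precursor_charge is not None and not 1 <= self.precursor_charge <= 6:
            raise ValueError(f"charge {self.precursor_charge} outside 1..6")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


def read_mgf(source: Union[str, os.PathLike, IO[str]]) -> list[MsmsSpectrum]:
    """Parse an MGF file or text stream into spectra, preserving order.

    Blocks without PEPMASS are skipped with a warning. Negative-charge
    blocks are skipped with a warning (positive-mode acquisition).
    Peaks are re-sorted ascending if the file is unsorted; the reader
    never drops or re-filters peaks.

    Raises
    ------
    MgfParseError
        On unparseable numeric fields or a truncated block, naming the
        block index.
    """
    spectra: list[MsmsSpectrum] = []
    block_index = 0
    try:
        with _pyteomics_mgf.read(source, use_index=False, convert_arrays=1) as reader:
            for entry in reader:
                block_index += 1
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    logger.warning("block %d has no PEPMASS; skipped", block_index)
                    continue
                charge = None
                charge_list = params.get("charge")
                if charge_list:
                    raw = int(charge_list[0])
                    if raw < 0:
                        logger.warning(
                            "block %d has negative charge %d; skipped",
                            block_index, raw,
                        )
                        continue
                    charge = raw
                rt = params.get("rtinseconds")
                spectra.append(
                    MsmsSpectrum(
                        scan_title=str(params.get("title", "")),
                        precursor_mz=float(pepmass[0]),
                        precursor_charge=charge,
                        retention_time=float(rt) if rt is not None else None,
                        mz=entry.get("m/z array", np.empty(0)),
                        intensity=entry.get("intensity array", np.empty(0)),
                        ordinal=len(spectra),
                    )
                )
    except (ValueError, _pyteomics_mgf.aux.PyteomicsError) as exc:
        if isinstance(exc, MgfParseError):
            raise
        raise MgfParseError(f"parse error in block {block_index + 1}: {exc}") from exc
    return spectra


def _format_mz(x: float) -> str:
    return f"{x:.6f}"


def write_mgf(spectra: Iterable[MsmsSpectrum], sink: Union[str, os.PathLike, IO[str]]) -> None:
    """Write spectra as MGF; round-trips losslessly via :func:`read_mgf`."""
    own = isinstance(sink, (str, os.PathLike))
    fh: IO[str] = open(sink, "w", encoding="utf-8") if own else sink  # type: ignore[arg-type]
    try:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.scan_title}\n")
            fh.write(f"PEPMASS={_format_mz(spec.precursor_mz)}\n")
            if spec.precursor_charge is not None:
                fh.write(f"CHARGE={spec.precursor_charge}+\n")
            if spec.retention_time is not None:
                fh.write(f"RTINSECONDS={spec.retention_time:.4f}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{_format_mz(mz)} {inten:.6g}\n")
            fh.write("END IONS\n")
    finally:
        if own:
            fh.close()


def rt_window_filter(
    spectra: Sequence[MsmsSpectrum],
    reference_rt: float,
    before: float,
    after: float,
) -> list[MsmsSpectrum]:
    """Keep spectra with RT in [reference − before, reference + after].

    Mirrors the protocol's chromatographic windowing around the free
    diagnostic peptide (modified species elute later, hence the
    asymmetric window). Spectra lacking a retention time are kept and
    counted in a warning. ``before``/``after`` are seconds and must be
    non-negative.
    """
    if before < 0 or after < 0:
        raise ValueError("window extents must be non-negative")
    lo, hi = reference_rt - before, reference_rt + after
    kept: list[MsmsSpectrum] = []
    n_missing = 0
    for spec in spectra:
        if spec.retention_time is None:
            n_missing += 1
            kept.append(spec)
        elif lo <= spec.retention_time <= hi:
            kept.append(spec)
    if n_missing:
        logger.warning("%d spectra lack retention time; kept unfiltered", n_missing)
    return kept
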