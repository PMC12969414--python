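"""Shared fixtures: the diagnostic peptide, noise-free spectrum builders."""

from pathlib import Path

import numpy as np
import pytest

from mr1scan import DiagnosticPeptide, MsmsSpectrum, fragment_ladder, mz_from_neutral

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def peptide() -> DiagnosticPeptide:
    return DiagnosticPeptide()


@pytest.fixture(scope="session")
def y_ladder(peptide):
    return fragment_ladder(peptide, series_set=("y",), max_fragment_charge=1)


@pytest.fixture
def make_adduct_spectrum(peptide, y_ladder):
    """Build a noise-free spectrum of the modified peptide.

    ``delta``: adduct Δ-mass (0 for the unmodified peptide);
    ``ion_labels``: which y-ions to implant (default all 12);
    ``charge``: precursor charge; ``mz_offset_ppm``: shift applied to
    every implanted fragment (for tolerance-boundary tests).
    """

    def _make(delta=0.0, ion_labels=None, charge=3, mz_offset_ppm=0.0,
              ordinal=0, rt=1800.0, title="synthetic"):
        ions = y_ladder if ion_labels is None else [
            ion for ion in y_ladder if ion.label in set(ion_labels)
        ]
        mz = np.array(
            [
                (ion.mz_unmodified + (delta / ion.charge if ion.contains_site else 0.0))
                * (1.0 + mz_offset_ppm * 1e-6)
                for ion in ions
            ]
        )
        return MsmsSpectrum(
            scan_title=title,
            precursor_mz=mz_from_neutral(peptide.neutral_mass + delta, charge),
            precursor_charge=charge,
            retention_time=rt,
            mz=mz,
            intensity=np.full(mz.shape, 1000.0),
            ordinal=ordinal,
        )

    return _make
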