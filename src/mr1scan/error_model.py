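"""Propagation of precursor mass error to inferred ligand masses.

The precursor tolerance applies to the whole cross-linked peptide ion
(~1.6–2.4 kDa), but the ligand is only a small slice of it, so the
relative error of the inferred ligand mass is amplified by the ratio of
total ion mass to ligand mass: a 5 ppm precursor error becomes ~200 ppm
on a 40 Da ligand. This motivates annotating at a wide global tolerance
(200 ppm) and filtering afterwards with the mass-dependent window this
module computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_core import OXYGEN_MASS, PROTON_MASS, DiagnosticPeptide

__all__ = ["ErrorModelSpec", "propagated_ppm", "tolerance_window", "error_table", "plot_error_table"]

DEFAULT_PPM_SETTINGS = (1.0, 3.0, 5.0, 10.0, 20.0, 50.0)


@dataclass(frozen=True)
class ErrorModelSpec:
    """Error-propagation setup.

    Defaults follow the screen's reference condition: the z=3 precursor
    of the cross-linked diagnostic peptide, mass-accuracy settings of
    1/3/5/10/20/50 ppm, and a ligand-size axis of 40–800 Da.
    """

    peptide_neutral_mass: float = DiagnosticPeptide().neutral_mass
    precursor_charge: int = 3
    precursor_ppm_settings: tuple[float, ...] = DEFAULT_PPM_SETTINGS
    ligand_mass_low: float = 40.0
    ligand_mass_high: float = 800.0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.precursor_ppm_settings):
            raise ValueError("ppm settings must be positive")
        if not 0 < self.ligand_mass_low < self.ligand_mass_high:
            raise ValueError("require 0 < low < high for the ligand mass range")
        if self.precursor_charge < 1:
            raise ValueError("charge must be ≥ 1")

    def precursor_neutral_mass(self, ligand_mass: float) -> float:
        """Neutral mass of the charged cross-linked precursor ion.

        Peptide + ligand − O (reduced Schiff base) + z charge-carrier
        protons; the ppm error acts on this whole ion mass.
        """
        return (
            self.peptide_neutral_mass
            + ligand_mass
            - OXYGEN_MASS
            + self.precursor_charge * PROTON_MASS
        )


def propagated_ppm(
    ligand_mass: float | np.ndarray,
    precursor_ppm: float,
    spec: ErrorModelSpec = ErrorModelSpec(),
) -> float | np.ndarray:
    """Relative error (ppm) of the inferred ligand mass.

    absolute error = precursor_ppm × 1e-6 × precursor ion mass; the
    result is that error expressed relative to the ligand mass. Strictly
    decreasing in ligand mass and linear in precursor_ppm.
    """
    ligand_mass = np.asarray(ligand_mass, dtype=float)
    if np.any(ligand_mass <= 0):
        raise ValueError("ligand mass must be positive")
    abs_error = precursor_ppm * 1e-6 * spec.precursor_neutral_mass(ligand_mass)
    out = abs_error / ligand_mass * 1e6
    return float(out) if out.ndim == 0 else out


def tolerance_window(
    ligand_mass: float,
    precursor_ppm: float,
    spec: ErrorModelSpec = ErrorModelSpec(),
) -> float:
    """Absolute symmetric ± window (Da) around an inferred ligand mass.

    Equal to propagated_ppm × 1e-6 × ligand mass — the absolute error
    lives on the precursor, so the window is (nearly) constant across
    ligand masses for a fixed setup.
    """
    return float(propagated_ppm(ligand_mass, precursor_ppm, spec)) * 1e-6 * ligand_mass


def error_table(
    spec: ErrorModelSpec = ErrorModelSpec(),
    grid_step: float = 1.0,
) -> pd.DataFrame:
    """Propagated error over a dense ligand-mass grid per ppm setting.

    Columns: ligand_mass (Da), precursor_ppm, propagated_ppm,
    window_da. Default 1 Da steps over 40–800 Da for each of the six
    mass-accuracy settings.
    """
    grid = np.arange(spec.ligand_mass_low, spec.ligand_mass_high + grid_step / 2, grid_step)
    frames = []
    for ppm in spec.precursor_ppm_settings:
        prop = propagated_ppm(grid, ppm, spec)
        frames.append(
            pd.DataFrame(
                {
                    "ligand_mass": grid,
                    "precursor_ppm": ppm,
                    "propagated_ppm": prop,
                    "window_da": prop * 1e-6 * grid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_error_table(table: pd.DataFrame, path: str) -> None:
    """Render the propagated-error curves, one panel per ppm setting."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    settings = sorted(table["precursor_ppm"].unique())
    ncols = 3
    nrows = -(-len(settings) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, ppm in zip(axes.ravel(), settings):
        sub = table[table["precursor_ppm"] == ppm]
        ax.plot(sub["ligand_mass"], sub["propagated_ppm"])
        ax.set_title(f"{ppm:g} ppm precursor accuracy")
        ax.set_xlabel("ligand mass (Da)")
        ax.set_ylabel("propagated error (ppm)")
    for ax in axes.ravel()[len(settings):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
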