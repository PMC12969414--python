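"""Closed-vs-open-search calibration of the reporter-ion cutoff.

The unmodified diagnostic peptide is abundant and fragments well, so a
"closed search" (records with |Δ| ≈ 0) accumulates spectra quickly at
high reporter thresholds and then plateaus. The "open search" (all
records, no Δ restriction) instead rises steeply once the threshold
drops into the regime where random peaks produce spurious matches. The
threshold at the transition — closed flat, open exploding — is a
practical, data-driven cutoff for Δ-mass assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_core import DiagnosticPeptide
from .deltascan import DeltaMassRecord, ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "split_closed_open",
    "cumulative_counts",
    "suggest_cutoff",
    "calibrate",
    "plot_curve",
]


@dataclass
class CalibrationCurve:
    """Cumulative spectrum counts per reporter threshold.

    ``thresholds`` run from the most to the least stringent (e.g. 12..1);
    counts at threshold k are the number of spectra with ≥ k matched
    reporters, so both sequences are non-decreasing along the list.
    """

    thresholds: list[int]
    closed_counts: list[int]
    open_counts: list[int]
    suggested_cutoff: int | None = None


def split_closed_open(
    records: Sequence[DeltaMassRecord],
    config: ScanConfig = ScanConfig(),
    peptide: DiagnosticPeptide = DiagnosticPeptide(),
) -> tuple[list[DeltaMassRecord], list[DeltaMassRecord]]:
    """Partition scanner records into the closed and open searches.

    Closed: |Δ| within ``closed_search_epsilon_ppm`` of zero, expressed
    in ppm of the peptide neutral mass (± instrument error). Open: all
    records — the closed set is a subset of the open set.
    """
    epsilon_da = config.closed_search_epsilon_ppm * 1e-6 * peptide.neutral_mass
    closed = [r for r in records if abs(r.delta_mass) <= epsilon_da]
    return closed, list(records)


def cumulative_counts(
    closed: Sequence[DeltaMassRecord],
    open_: Sequence[DeltaMassRecord],
    thresholds: Sequence[int] | None = None,
) -> CalibrationCurve:
    """Cumulative counts of spectra with ≥ k reporters, per threshold k.

    Thresholds default to ladder size .. 1 (12..1 for the default
    peptide's y-series), given as a descending integer sequence.
    """
    if thresholds is None:
        size = 12
        for r in list(closed) + list(open_):
            size = len(r.reporter_flags)
            break
        thresholds = list(range(size, 0, -1))
    thresholds = [int(t) for t in thresholds]
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    closed_counts = [sum(1 for r in closed if r.n_fragments >= k) for k in thresholds]
    open_counts = [sum(1 for r in open_ if r.n_fragments >= k) for k in thresholds]
    return CalibrationCurve(thresholds, closed_counts, open_counts)


def _relative_increase(counts: Sequence[int], i: int) -> float:
    """Relative rise of a cumulative count across step i → i+1."""
    prev, cur = counts[i], counts[i + 1]
    if prev > 0:
        return (cur - prev) / prev
    return float("inf") if cur > 0 else 0.0


def suggest_cutoff(curve: CalibrationCurve, ratio_threshold: float = 2.0) -> int:
    """Data-driven reporter-ion cutoff from the closed/open transition.

    A step k → k−1 qualifies when the open counts' relative increase
    exceeds ``ratio_threshold`` times the closed counts' relative
    increase — the open search rising while the closed search stays
    comparatively flat. Among qualifying steps the one with the
    steepest open rise wins (the noise flood dominates any trickle of
    genuine adducts entering at high thresholds) and its upper
    threshold k is returned: spectra with ≥ k reporters sit above the
    transition. If no step qualifies (degenerate or identical curves)
    the minimum threshold is returned with a warning; the full curve
    should then be inspected visually.
    """
    if len(curve.thresholds) < 3:
        raise ValueError("need at least 3 thresholds")
    best_k: int | None = None
    best_rise = 0.0
    for i in range(len(curve.thresholds) - 1):
        open_rise = _relative_increase(curve.open_counts, i)
        closed_rise = _relative_increase(curve.closed_counts, i)
        if open_rise > ratio_threshold * closed_rise and open_rise > best_rise:
            best_k = curve.thresholds[i]
            best_rise = open_rise
    if best_k is None:
        best_k = curve.thresholds[-1]
        logger.warning(
            "no closed/open transition found; falling back to minimum threshold %d",
            best_k,
        )
    curve.suggested_cutoff = best_k
    return best_k


def calibrate(
    records: Sequence[DeltaMassRecord],
    config: ScanConfig = ScanConfig(),
    peptide: DiagnosticPeptide = DiagnosticPeptide(),
    thresholds: Sequence[int] | None = None,
    ratio_threshold: float = 2.0,
) -> CalibrationCurve:
    """End-to-end calibration: split, count, and suggest a cutoff."""
    closed, open_ = split_closed_open(records, config, peptide)
    curve = cumulative_counts(closed, open_, thresholds)
    suggest_cutoff(curve, ratio_threshold)
    return curve


def plot_curve(curve: CalibrationCurve, path: str) -> None:
    """Two-panel bar chart of the closed and open cumulative counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    x = np.arange(len(curve.thresholds))
    for ax, counts, title in (
        (axes[0], curve.closed_counts, "closed search (|Δ| ≈ 0)"),
        (axes[1], curve.open_counts, "open search (all Δ)"),
    ):
        ax.bar(x, counts)
        for xi, c in zip(x, counts):
            ax.text(xi, c, str(c), ha="center", va="bottom", fontsize=7)
        ax.set_xticks(x)
        ax.set_xticklabels([f"≥{t}" for t in curve.thresholds], rotation=45)
        ax.set_xlabel("reporter-ion threshold")
        ax.set_ylabel("cumulative spectra")
        ax.set_title(title)
    if curve.suggested_cutoff is not None:
        fig.suptitle(f"suggested cutoff: ≥{curve.suggested_cutoff} reporters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
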