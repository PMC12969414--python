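"""Compound-mass annotation and candidate shortlisting.

A local stand-in for a batch neutral-mass search against metabolite
databases: inferred free-ligand masses (Delta_Mass_Oxygen values) are
matched against user-supplied compound tables at a wide global ppm
tolerance, filtered to the mass-dependent propagated-error window, and
ranked by the strength of their Δ-mass evidence (reporter counts,
supporting spectra, retention-time consistency) with optional
plausibility rules on boolean compound flags.

Mass-only matching cannot distinguish structural isomers; hits are
candidates for biochemical validation, not identifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import FormulaError, parse_formula
from .deltascan import DeltaMassRecord
from .error_model import ErrorModelSpec, propagated_ppm

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "AnnotationHit",
    "PlausibilityRules",
    "load_compound_table",
    "batch_match",
    "apply_mass_window_filter",
    "cluster_ligand_masses",
    "shortlist",
]

_RESERVED_COLUMNS = {"name", "formula", "monoisotopic_mass", "source_db"}


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate-ligand database entry."""

    name: str
    monoisotopic_mass: float
    formula: str | None = None
    source_db: str = ""
    plausibility_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic mass must be positive")


@dataclass
class AnnotationHit:
    """A mass match between a query and a compound."""

    query_mass: float
    compound: CompoundRecord
    ppm_error: float  # signed, relative to the compound (theoretical) mass
    within_propagated_window: bool | None = None


@dataclass(frozen=True)
class PlausibilityRules:
    """Boolean-flag rules applied during shortlisting.

    ``require``: flags that must be True (a compound carrying the flag
    as False is excluded; compounds without the flag are kept — absence
    of evidence is not treated as implausibility).
    ``exclude``: flags whose True value excludes a compound.
    """

    require: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()

    def reason_to_exclude(self, compound: CompoundRecord) -> str | None:
        for flag in self.require:
            if compound.plausibility_flags.get(flag) is False:
                return f"required flag {flag!r} is false"
        for flag in self.exclude:
            if compound.plausibility_flags.get(flag) is True:
                return f"exclusion flag {flag!r} is true"
        return None


def _coerce_bool(value) -> bool | None:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"true", "yes", "1"}:
            return True
        if v in {"false", "no", "0"}:
            return False
    return None


def load_compound_table(source) -> list[CompoundRecord]:
    """Read a delimited compound table (comma or tab separated).

    Needs a ``name`` column plus ``formula`` and/or ``monoisotopic_mass``;
    masses are derived from the formula when absent. Extra columns with
    boolean-like values become plausibility flags. Rows that resolve to
    no mass (missing both, or malformed formula) are skipped with a
    warning.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    if "name" not in df.columns:
        raise ValueError("compound table needs a 'name' column")
    flag_columns = [c for c in df.columns if c not in _RESERVED_COLUMNS]

    records: list[CompoundRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        name = str(row["name"]).strip()
        formula = None
        if "formula" in df.columns and pd.notna(row.get("formula")):
            formula = str(row["formula"]).strip() or None
        mass = None
        if "monoisotopic_mass" in df.columns and pd.notna(row.get("monoisotopic_mass")):
            mass = float(row["monoisotopic_mass"])
        if mass is None and formula is not None:
            try:
                mass = parse_formula(formula)
            except FormulaError as exc:
                logger.warning("row %d (%s): %s; skipped", idx, name, exc)
                n_skipped += 1
                continue
        if mass is None:
            logger.warning("row %d (%s): neither formula nor mass; skipped", idx, name)
            n_skipped += 1
            continue
        flags: dict[str, bool] = {}
        for col in flag_columns:
            val = _coerce_bool(row.get(col))
            if val is not None:
                flags[col] = val
        records.append(
            CompoundRecord(
                name=name,
                monoisotopic_mass=mass,
                formula=formula,
                source_db=str(row.get("source_db", "") or ""),
                plausibility_flags=flags,
            )
        )
    if n_skipped:
        logger.warning("skipped %d of %d compound rows", n_skipped, len(df))
    return records


def batch_match(
    query_masses: Sequence[float],
    compounds: Sequence[CompoundRecord],
    tolerance_ppm: float = 200.0,
) -> dict[float, list[AnnotationHit]]:
    """Match each query mass against the compound table.

    For each query, all compounds with |ppm error| ≤ tolerance, sorted
    by |ppm error| ascending (ppm relative to the theoretical compound
    mass, the metabolomics convention). Queries with no hits map to
    empty lists. The default 200 ppm is the recommended global search
    tolerance; mass-dependent filtering comes afterwards.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    out: dict[float, list[AnnotationHit]] = {}
    for q in query_masses:
        hits = []
        for comp in compounds:
            ppm = (q - comp.monoisotopic_mass) / comp.monoisotopic_mass * 1e6
            if abs(ppm) <= tolerance_ppm:
                hits.append(AnnotationHit(query_mass=q, compound=comp, ppm_error=ppm))
        hits.sort(key=lambda h: (abs(h.ppm_error), h.compound.name))
        out[q] = hits
    return out


def apply_mass_window_filter(
    hits: Iterable[AnnotationHit],
    error_model_spec: ErrorModelSpec = ErrorModelSpec(),
    precursor_ppm: float = 5.0,
) -> list[AnnotationHit]:
    """Set ``within_propagated_window`` on each hit.

    A hit survives when its |ppm error| does not exceed the propagated
    ligand-mass error expected at the stated precursor accuracy for a
    compound of that mass — wide for small ligands, narrow for large.
    """
    out = []
    for hit in hits:
        window = propagated_ppm(hit.compound.monoisotopic_mass, precursor_ppm, error_model_spec)
        hit.within_propagated_window = abs(hit.ppm_error) <= window
        out.append(hit)
    return out


def cluster_ligand_masses(
    masses: Sequence[float],
    linkage_tolerance: float = 0.01,
) -> list[list[int]]:
    """Group repeated ligand-mass observations by single-linkage in Da.

    Sorted masses are split wherever consecutive values differ by more
    than the tolerance (default 0.01 Da, below the propagated window of
    any in-range ligand at 5 ppm). Returns index groups into ``masses``.
    """
    if not len(masses):
        return []
    order = np.argsort(masses, kind="stable")
    clusters: list[list[int]] = [[int(order[0])]]
    for prev, cur in zip(order[:-1], order[1:]):
        if masses[cur] - masses[prev] > linkage_tolerance:
            clusters.append([])
        clusters[-1].append(int(cur))
    return clusters


def shortlist(
    records: Sequence[DeltaMassRecord],
    compounds: Sequence[CompoundRecord],
    rules: PlausibilityRules = PlausibilityRules(),
    tolerance_ppm: float = 200.0,
    precursor_ppm: float = 5.0,
    error_model_spec: ErrorModelSpec = ErrorModelSpec(),
    linkage_tolerance: float = 0.01,
) -> pd.DataFrame:
    """Combine scanner evidence with compound annotation into a ranking.

    Passing records are clustered by Delta_Mass_Oxygen, each cluster's
    mean mass is annotated against the compound table, hits are filtered
    to the propagated-error window and the plausibility rules, and each
    candidate is scored with its supporting evidence: stringent-pass
    count, supporting-spectrum count, max/mean "#Fragments" and RT
    spread. Sorted by (stringent passes desc, supporting spectra desc,
    max #Fragments desc, RT spread asc, name asc) — a deterministic,
    pure function of its inputs.
    """
    passing = [r for r in records if r.passes_filters]
    columns = [
        "compound", "formula", "compound_mass", "source_db", "query_mass",
        "ppm_error", "within_propagated_window", "n_spectra", "n_stringent",
        "max_fragments", "mean_fragments", "rt_spread_s",
        "excluded", "exclusion_reason",
    ]
    if not passing:
        return pd.DataFrame(columns=columns)

    masses = [r.delta_mass_oxygen for r in passing]
    clusters = cluster_ligand_masses(masses, linkage_tolerance)
    rows = []
    for idx_group in clusters:
        members = [passing[i] for i in idx_group]
        query = float(np.mean([m.delta_mass_oxygen for m in members]))
        rts = [m.retention_time for m in members if m.retention_time is not None]
        rt_spread = float(max(rts) - min(rts)) if len(rts) >= 2 else 0.0
        n_stringent = sum(1 for m in members if m.stringent)
        hits = batch_match([query], compounds, tolerance_ppm)[query]
        hits = apply_mass_window_filter(hits, error_model_spec, precursor_ppm)
        for hit in hits:
            reason = rules.reason_to_exclude(hit.compound)
            if not hit.within_propagated_window:
                reason = reason or "outside propagated mass-error window"
            rows.append(
                {
                    "compound": hit.compound.name,
                    "formula": hit.compound.formula or "",
                    "compound_mass": hit.compound.monoisotopic_mass,
                    "source_db": hit.compound.source_db,
                    "query_mass": query,
                    "ppm_error": hit.ppm_error,
                    "within_propagated_window": bool(hit.within_propagated_window),
                    "n_spectra": len(members),
                    "n_stringent": n_stringent,
                    "max_fragments": max(m.n_fragments for m in members),
                    "mean_fragments": float(np.mean([m.n_fragments for m in members])),
                    "rt_spread_s": rt_spread,
                    "excluded": reason is not None,
                    "exclusion_reason": reason or "",
                }
            )
    table = pd.DataFrame(rows, columns=columns)
    if table.empty:
        return table
    table = table.sort_values(
        by=["excluded", "n_stringent", "n_spectra", "max_fragments", "rt_spread_s", "compound"],
        ascending=[True, False, False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return table
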