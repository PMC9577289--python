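"""Marker-gene immune cell-type scores and the TILs composite.

A cell type's score is the arithmetic mean of its retained marker genes'
log2 normalized expression — a relative-abundance proxy on the log2 scale,
not an absolute fraction.  The tumour-infiltrating-lymphocyte (TILs) score
averages the cell scores whose Pearson correlation with the pan-leukocyte
reference gene (PTPRC/CD45) exceeds ``r_min`` (default 0.6).  Relative
abundances ("cell/TILs ratios") are score minus TILs, i.e. the log2 of a
ratio, which makes them invariant to global expression shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerPanel


@dataclass
class CellScoreTable:
    """Per-sample cell-type scores plus the TILs composite and relatives."""

    scores: pd.DataFrame                      # samples x cell types
    tils: pd.Series | None = None             # per-sample TILs score
    relative: pd.DataFrame | None = None      # scores minus TILs
    tils_members: dict[str, float] = field(default_factory=dict)  # cell -> r
    unscorable: list[str] = field(default_factory=list)


def marker_qc_filter(expr, panel: MarkerPanel, threshold: float
                     ) -> tuple[MarkerPanel, dict]:
    """Drop markers whose mean log2 expression does not exceed ``threshold``.

    Returns the filtered panel and a report ``{cell_type: dropped genes}``;
    cell types that lose every marker (or have none measured) are flagged
    unscorable under the ``None`` cell-type key convention of the report's
    ``unscorable`` entry.
    """
    values = expr.values
    means = values.mean(axis=0)
    kept: dict[str, list[str]] = {}
    dropped: dict[str, list[str]] = {}
    unscorable: list[str] = []
    for cell, genes in panel.cell_types.items():
        present = [g for g in genes if g in values.columns]
        missing = [g for g in genes if g not in values.columns]
        keep = [g for g in present if means[g] > threshold]
        drop = [g for g in present if means[g] <= threshold] + missing
        if keep:
            kept[cell] = keep
        else:
            unscorable.append(cell)
        if drop:
            dropped[cell] = drop
    filtered = MarkerPanel(
        cell_types=kept,
        reference_gene=panel.reference_gene,
        cytotoxic_genes=panel.cytotoxic_genes,
    )
    report = {"dropped": dropped, "unscorable": unscorable, "threshold": threshold}
    return filtered, report


def compute_cell_scores(expr, panel: MarkerPanel) -> CellScoreTable:
    """Mean log2 marker expression per sample per cell type."""
    values = expr.values
    cols = {}
    for cell, genes in panel.cell_types.items():
        present = [g for g in genes if g in values.columns]
        if present:
            cols[cell] = values[present].mean(axis=1)
    if not cols:
        raise ValueError("no scorable cell types: panel empty after QC")
    scores = pd.DataFrame(cols)
    unscorable = [c for c in panel.cell_types if c not in cols]
    return CellScoreTable(scores=scores, unscorable=unscorable)


def compute_tils_score(table: CellScoreTable, expr, reference_gene: str = "PTPRC",
                       r_min: float = 0.6) -> CellScoreTable:
    """Correlation-gated TILs score.

    Includes every cell type whose score correlates with the reference
    gene's expression at Pearson r > ``r_min``; the TILs score is the mean of
    the included scores.  Fills ``tils``, ``tils_members`` and ``relative``
    on a copy of ``table``.
    """
    values = expr.values
    if reference_gene not in values.columns:
        raise ValueError(f"reference gene {reference_gene!r} not in expression matrix")
    ref = values[reference_gene]
    members: dict[str, float] = {}
    for cell in table.scores.columns:
        r = float(np.corrcoef(table.scores[cell], ref)[0, 1])
        if np.isfinite(r) and r > r_min:
            members[cell] = r
    if not members:
        warnings.warn(
            f"TILs score undefined: no cell score correlates with "
            f"{reference_gene} at r > {r_min}",
            stacklevel=2,
        )
        return CellScoreTable(scores=table.scores, tils=None, relative=None,
                              tils_members={}, unscorable=table.unscorable)
    tils = table.scores[list(members)].mean(axis=1)
    relative = table.scores.sub(tils, axis=0)
    return CellScoreTable(scores=table.scores, tils=tils, relative=relative,
                          tils_members=members, unscorable=table.unscorable)


def cytotoxic_composite(expr, genes) -> pd.Series:
    """Mean log2 expression of the cytotoxic gene set (NK/CD8/Tgd shared)."""
    genes = list(genes)
    if not genes:
        raise ValueError("cytotoxic gene list is empty")
    values = expr.values
    present = [g for g in genes if g in values.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"cytotoxic genes missing from matrix, dropped: {missing}",
                      stacklevel=2)
    if not present:
        raise ValueError("no cytotoxic genes present in expression matrix")
    return values[present].mean(axis=1)


def relative_scores(table: CellScoreTable) -> pd.DataFrame:
    """Cell/TILs relative abundances: score minus TILs on the log2 scale."""
    if table.tils is None:
        raise ValueError("TILs score undefined; cannot form relative scores")
    return table.scores.sub(table.tils, axis=0)


def score_pipeline(expr, panel: MarkerPanel, qc_threshold: float,
                   r_min: float = 0.6) -> CellScoreTable:
    """QC-filter the panel, score cell types, gate the TILs composite."""
    filtered, _ = marker_qc_filter(expr, panel, qc_threshold)
    table = compute_cell_scores(expr, filtered)
    return compute_tils_score(table, expr, reference_gene=panel.reference_gene,
                              r_min=r_min)
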