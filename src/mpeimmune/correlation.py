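"""Immunomodulator correlation structure and per-cluster expression profiles.

Pairwise Pearson correlations over the modulator genes, with two-sided
t-distribution p-values, BH-FDR over the upper-triangle family (diagonal
excluded) and masking of pairs at FDR >= 0.01.  Display order comes from
Ward clustering of the correlation-matrix rows under Euclidean distance.
Cluster mean profiles average log2 expression per gene within each patient
cluster and z-score per gene across clusters for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import WARD_D, cut_k, ward_linkage  # noqa: F401  (cut_k re-exported)
from .diffexpr import bh_adjust

FDR_MASK_THRESHOLD = 0.01


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r with p/FDR matrices, mask and display order."""

    genes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    fdr: pd.DataFrame
    mask: pd.DataFrame          # True where the pair shows no correlation
    display_order: list[str]

    def long_format(self) -> pd.DataFrame:
        """Upper-triangle pairs as rows: gene1, gene2, r, p, fdr, masked."""
        rows = []
        for i, g1 in enumerate(self.genes):
            for g2 in self.genes[i + 1:]:
                rows.append(
                    {
                        "gene1": g1, "gene2": g2,
                        "r": self.r.loc[g1, g2], "p": self.p.loc[g1, g2],
                        "fdr": self.fdr.loc[g1, g2],
                        "masked": bool(self.mask.loc[g1, g2]),
                    }
                )
        return pd.DataFrame(rows)


def pearson_matrix(expr, genes=None, fdr_threshold: float = FDR_MASK_THRESHOLD
                   ) -> CorrelationMatrix:
    """Pairwise Pearson correlation of (a gene subset of) an expression matrix."""
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    if genes is not None:
        present = [g for g in genes if g in values.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"modulator genes missing from matrix, dropped: {missing}",
                          stacklevel=2)
        values = values[present]
    n = len(values)
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    sd = values.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"zero-variance genes excluded: {constant}", stacklevel=2)
        values = values.drop(columns=constant)
    gene_list = list(values.columns)
    m = len(gene_list)
    if m < 2:
        raise ValueError("fewer than 2 variable genes")

    r = np.corrcoef(values.to_numpy(), rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    # two-sided p from t = r sqrt((n-2)/(1-r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(m, k=1)
    fdr = np.zeros_like(p)
    fdr_flat = bh_adjust(p[iu])
    fdr[iu] = fdr_flat
    fdr[(iu[1], iu[0])] = fdr_flat
    mask = fdr >= fdr_threshold
    np.fill_diagonal(mask, False)

    linkage = ward_linkage(r, variant=WARD_D)
    order = _leaf_order(linkage, m)
    display_order = [gene_list[i] for i in order]

    idx = pd.Index(gene_list, name="gene")
    return CorrelationMatrix(
        genes=gene_list,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        fdr=pd.DataFrame(fdr, index=idx, columns=idx),
        mask=pd.DataFrame(mask, index=idx, columns=idx),
        display_order=display_order,
    )


def _leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order by depth-first traversal of the merge tree."""
    children = {n + i: (int(l), int(r)) for i, (l, r, _, _) in enumerate(linkage)}
    order: list[int] = []
    stack = [n + len(linkage) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            left, right = children[node]
            stack.append(right)
            stack.append(left)
    return order


def cluster_mean_profiles(expr, clusters: pd.DataFrame, genes=None
                          ) -> pd.DataFrame:
    """Per-cluster mean log2 expression, z-scored per gene across clusters.

    Returns genes x clusters, rows and columns ordered by Ward/Euclidean
    clustering of the profile matrix.  Constant genes get z-score 0; empty
    clusters are dropped with a warning.
    """
    values = expr.values if hasattr(expr, "values") and not isinstance(expr, pd.DataFrame) else expr
    if genes is not None:
        present = [g for g in genes if g in values.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"profile genes missing from matrix, dropped: {missing}",
                          stacklevel=2)
        values = values[present]
    labels = clusters["cluster"] if "cluster" in clusters else clusters
    common = values.index.intersection(labels.index)
    values = values.loc[common]
    labels = labels.loc[common]
    means = values.groupby(labels).mean().T  # genes x clusters
    empty = [c for c in ("C1", "C2", "C3", "C4") if c not in means.columns]
    if empty:
        warnings.warn(f"empty clusters dropped from profiles: {empty}", stacklevel=2)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)

    if len(z) > 2:
        row_link = ward_linkage(z.to_numpy(), variant=WARD_D)
        z = z.iloc[_leaf_order(row_link, len(z))]
    if z.shape[1] > 2:
        col_link = ward_linkage(z.to_numpy().T, variant=WARD_D)
        z = z.iloc[:, _leaf_order(col_link, z.shape[1])]
    return z
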