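"""Hot/cold adaptive-innate patient stratification by Ward clustering.

The gene side: the immune panel (74 genes by default) is z-scored per gene
and Ward-clustered over sample space; the k=2 cut yields gene clusters A
(adaptive + cytotoxic, identified by correlation with seed CD8/NK/B markers)
and B (innate + other T cells).  The patient side: Ward k=2 on cluster-A
genes splits hot vs cold; within each temperature stratum, Ward k=2 on
cluster-B genes splits innate+ vs innate-.  Labels compose as C1 = (hot,
innate+), C2 = (hot, innate-), C3 = (cold, innate-), C4 = (cold, innate+).

Two Ward variants are provided via the Lance–Williams recurrence:
``ward_d`` applies the update to unsquared Euclidean distances (the classic
``ward.D`` behaviour) and ``ward_d2`` to squared distances with square-root
merge heights (scipy's / ``ward.D2``'s behaviour).  Ties merge the pair with
the smallest indices for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform

WARD_D = "ward_d"
WARD_D2 = "ward_d2"

HOT, COLD = "hot", "cold"
INNATE_PLUS, INNATE_MINUS = "plus", "minus"

# (temperature, innate) -> C label; the defining invariant of the assignment
CLUSTER_OF = {
    (HOT, INNATE_PLUS): "C1",
    (HOT, INNATE_MINUS): "C2",
    (COLD, INNATE_MINUS): "C3",
    (COLD, INNATE_PLUS): "C4",
}


@dataclass
class GenePartition:
    """k=2 gene partition with its dendrogram (scipy linkage format)."""

    cluster_A_genes: list[str]
    cluster_B_genes: list[str]
    linkage: np.ndarray


def ward_linkage(vectors: np.ndarray, variant: str = WARD_D) -> np.ndarray:
    """Agglomerate ``vectors`` (n x p) with Ward's criterion.

    Returns an (n-1) x 4 scipy-style linkage matrix (left, right, height,
    size).  The Lance–Williams Ward update
    ``d(k, i∪j) = [(n_i+n_k) d_ki + (n_j+n_k) d_kj − n_k d_ij] / (n_i+n_j+n_k)``
    is applied to unsquared Euclidean distances for ``ward_d`` and to squared
    distances (heights reported as square roots) for ``ward_d2``.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need >= 2 vectors")
    if not np.isfinite(vectors).all():
        raise ValueError("non-finite input to ward_linkage")
    if variant not in (WARD_D, WARD_D2):
        raise ValueError(f"unknown ward variant {variant!r}")
    dist = squareform(pdist(vectors))
    if variant == WARD_D2:
        dist = dist ** 2
    return _lance_williams_ward(dist, sqrt_heights=(variant == WARD_D2))


def _lance_williams_ward(dist: np.ndarray, sqrt_heights: bool) -> np.ndarray:
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = {i: 1 for i in range(n)}
    node_id = {i: i for i in range(n)}          # row -> current cluster id
    active = list(range(n))
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        # smallest distance; argmin's row-major scan breaks ties by the
        # smallest (i, j) index pair
        rows = np.asarray(active)
        sub = d[np.ix_(rows, rows)]
        ai, aj = divmod(int(np.argmin(sub)), len(rows))
        if ai > aj:
            ai, aj = aj, ai
        i, j = int(rows[ai]), int(rows[aj])
        height = d[i, j]
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            d[i, k] = d[k, i] = (
                (ni + nk) * d[k, i] + (nj + nk) * d[k, j] - nk * height
            ) / (ni + nj + nk)
        left, right = sorted((node_id[i], node_id[j]))
        merges[step] = (left, right,
                        np.sqrt(height) if sqrt_heights else height, ni + nj)
        size[i] = ni + nj
        node_id[i] = next_id
        next_id += 1
        active.remove(j)
    return merges


def cut_k(linkage: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into ``k`` flat clusters (labels 1..k)."""
    return fcluster(linkage, t=k, criterion="maxclust")


def zscore_genes(expr_values: pd.DataFrame) -> pd.DataFrame:
    """z-score each gene (column) across samples; constant genes map to 0."""
    mu = expr_values.mean(axis=0)
    sd = expr_values.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (expr_values - mu) / sd


def partition_genes(expr, panel_genes, seed_genes, variant: str = WARD_D
                    ) -> GenePartition:
    """Ward k=2 partition of panel genes into adaptive (A) vs innate (B).

    Genes are z-scored across samples and clustered as vectors over sample
    space.  The cluster whose genes correlate more strongly on average with
    the adaptive/cytotoxic ``seed_genes`` is labelled A.
    """
    values = expr.values
    present = [g for g in panel_genes if g in values.columns]
    missing = sorted(set(panel_genes) - set(present))
    if missing:
        warnings.warn(f"panel genes missing from matrix, dropped: {missing}",
                      stacklevel=2)
    if len(present) < 2:
        raise ValueError("fewer than 2 panel genes present")
    z = zscore_genes(values[present])
    linkage = ward_linkage(z.T.to_numpy(), variant=variant)
    labels = cut_k(linkage, 2)
    groups = {lab: [g for g, l in zip(present, labels) if l == lab]
              for lab in (1, 2)}
    seeds = [g for g in seed_genes if g in values.columns]
    if not seeds:
        raise ValueError("no seed genes present for A/B labelling")
    corr = values[present + [g for g in seeds if g not in present]].corr()

    def seed_affinity(genes: list[str]) -> float:
        return float(corr.loc[genes, seeds].to_numpy().mean())

    a_lab = max(groups, key=lambda lab: seed_affinity(groups[lab]))
    b_lab = 1 if a_lab == 2 else 2
    return GenePartition(cluster_A_genes=groups[a_lab],
                         cluster_B_genes=groups[b_lab], linkage=linkage)


def _split_two(z: pd.DataFrame, samples, variant: str) -> pd.Series:
    """Ward k=2 over the given samples on the given (z-scored) gene block."""
    sub = z.loc[samples]
    labels = cut_k(ward_linkage(sub.to_numpy(), variant=variant), 2)
    return pd.Series(labels, index=sub.index)


def assign_patients(expr, partition: GenePartition, variant: str = WARD_D,
                    method: str = "dendrogram") -> pd.DataFrame:
    """Two-level patient assignment into hot/cold x innate± (C1–C4).

    ``method='dendrogram'`` (default) uses Ward k=2 cuts; ``method='median'``
    splits at the median of the per-patient mean block expression.  Returns
    a DataFrame indexed by sample with columns ``temperature``, ``innate``,
    ``cluster``.
    """
    values = expr.values
    zA = zscore_genes(values[partition.cluster_A_genes])
    zB = zscore_genes(values[partition.cluster_B_genes])
    mean_a = zA.mean(axis=1)
    mean_b = zB.mean(axis=1)
    samples = values.index

    if method == "median":
        hot_mask = mean_a > mean_a.median()
    elif method == "dendrogram":
        split = _split_two(zA, samples, variant)
        hot_lab = max((1, 2), key=lambda lab: mean_a[split == lab].mean())
        hot_mask = split == hot_lab
    else:
        raise ValueError(f"unknown patient split method {method!r}")

    temperature = pd.Series(np.where(hot_mask, HOT, COLD), index=samples)
    innate = pd.Series(index=samples, dtype=object)
    overall_median_b = mean_b.median()
    for temp in (HOT, COLD):
        stratum = samples[temperature == temp]
        if len(stratum) < 2:
            if len(stratum) == 1:
                warnings.warn(
                    f"{temp} stratum has a single patient; assigned by "
                    "comparing its innate-block mean to the overall median",
                    stacklevel=2,
                )
                innate.loc[stratum] = (
                    INNATE_PLUS if mean_b[stratum[0]] > overall_median_b
                    else INNATE_MINUS
                )
            continue
        if method == "median":
            med = mean_b[stratum].median()
            sub = pd.Series(
                np.where(mean_b[stratum] > med, INNATE_PLUS, INNATE_MINUS),
                index=stratum,
            )
        else:
            split = _split_two(zB, stratum, variant)
            plus_lab = max((1, 2), key=lambda lab: mean_b[split.index[split == lab]].mean())
            sub = pd.Series(
                np.where(split == plus_lab, INNATE_PLUS, INNATE_MINUS),
                index=stratum,
            )
        innate.loc[stratum] = sub

    out = pd.DataFrame({"temperature": temperature, "innate": innate})
    out["cluster"] = [CLUSTER_OF[(t, i)] for t, i in zip(out.temperature, out.innate)]
    out.index.name = "sample_id"
    return out
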