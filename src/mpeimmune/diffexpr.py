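"""Negative-binomial Wald differential expression between two patient groups.

A deliberately self-contained scheme on raw endogenous counts:

1. median-of-ratios size factors (reference = per-gene geometric mean over
   zero-free genes);
2. per-gene method-of-moments dispersion on normalized counts, pooled
   within groups, floored at ``ALPHA_FLOOR`` (no shrinkage across genes, no
   fold-change moderation, no independent filtering);
3. per-gene Wald test of the log2 fold change with the NB delta-method
   standard error ``sqrt(sum_g (1/n_g) (1/mu_g + alpha)) / ln 2``;
4. Benjamini–Hochberg FDR across tested genes.

A gene is called significant when |log2FC| >= 1 and FDR < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 1e-8
LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
GROUP_MEAN_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (samples x genes counts).

    Reference = per-gene geometric mean across samples over genes with no
    zero counts; each sample's factor is the median ratio of its counts to
    the reference over those genes.  If no gene is zero-free, geometric
    means fall back to positive counts only, with a warning.
    """
    vals = counts.to_numpy(dtype=float)
    zero_free = (vals > 0).all(axis=0)
    if zero_free.any():
        ref = np.exp(np.log(vals[:, zero_free]).mean(axis=0))
        ratios = vals[:, zero_free] / ref
    else:
        warnings.warn("no zero-free gene; using positive counts only for the "
                      "geometric-mean reference", stacklevel=2)
        with np.errstate(divide="ignore"):
            logs = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=0))
        usable = np.isfinite(ref) & (ref > 0)
        if not usable.any():
            raise ValueError("cannot compute size factors: all counts zero")
        with np.errstate(invalid="ignore"):
            ratios = np.where(vals[:, usable] > 0,
                              vals[:, usable] / ref[usable], np.nan)
    factors = np.nanmedian(ratios, axis=1)
    if (~np.isfinite(factors) | (factors <= 0)).any():
        raise ValueError("non-positive size factor; counts too sparse")
    return pd.Series(factors, index=counts.index, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series,
                        sf: pd.Series | None = None,
                        alpha_floor: float = ALPHA_FLOOR) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    ``alpha = max((pooled within-group variance - mean) / mean^2, floor)``;
    all-zero genes sit at the floor.
    """
    levels = _two_levels(groups)
    if sf is None:
        sf = size_factors(counts)
    norm = counts.div(sf, axis=0)
    mean_all = norm.mean(axis=0).to_numpy()
    pooled_var = np.zeros(counts.shape[1])
    total_df = 0
    for lev in levels:
        sub = norm.loc[groups == lev]
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
        pooled_var += sub.var(axis=0, ddof=1).to_numpy() * (n - 1)
        total_df += n - 1
    pooled_var /= total_df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean_all) / mean_all ** 2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    alpha = np.maximum(alpha, alpha_floor)
    return pd.Series(alpha, index=counts.columns, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series,
                 sf: pd.Series | None = None,
                 dispersions: pd.Series | None = None,
                 levels=None) -> pd.DataFrame:
    """NB Wald test per gene between the two levels of ``groups``.

    ``groups`` is indexed by sample; ``levels`` fixes the contrast order
    (fold change = ``levels[1]`` over ``levels[0]``; default: sorted level
    names).  Returns a DataFrame with columns ``base_mean, log2_fc, se,
    wald_p, fdr, significant``.
    """
    if levels is None:
        levels = _two_levels(groups)
    elif sorted(levels) != sorted(_two_levels(groups)):
        raise ValueError("levels must name the two group labels")
    counts = counts.loc[groups.index]
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, groups, sf=sf)
    norm = counts.div(sf.loc[counts.index], axis=0)
    g0 = norm.loc[groups == levels[0]]
    g1 = norm.loc[groups == levels[1]]
    n0, n1 = len(g0), len(g1)
    if min(n0, n1) < 2:
        raise ValueError("each group needs >= 2 samples")
    mu0 = g0.mean(axis=0).to_numpy()
    mu1 = g1.mean(axis=0).to_numpy()
    zero = (mu0 == 0) | (mu1 == 0)
    mu0 = np.where(zero, mu0 + GROUP_MEAN_PSEUDOCOUNT, mu0)
    mu1 = np.where(zero, mu1 + GROUP_MEAN_PSEUDOCOUNT, mu1)
    alpha = dispersions.to_numpy()
    log2_fc = np.log2(mu1 / mu0)
    se = np.sqrt((1.0 / n0) * (1.0 / mu0 + alpha)
                 + (1.0 / n1) * (1.0 / mu1 + alpha)) / np.log(2.0)
    z = log2_fc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(wald_p)
    out = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=0).to_numpy(),
            "log2_fc": log2_fc,
            "se": se,
            "wald_p": wald_p,
            "fdr": fdr,
            "significant": (np.abs(log2_fc) >= LFC_THRESHOLD) & (fdr < FDR_THRESHOLD),
        },
        index=pd.Index(counts.columns, name="gene"),
    )
    return out


def survival_groups(cohort: pd.DataFrame, cutoff_days: float = 90.0
                    ) -> tuple[pd.Series, list[str]]:
    """Long vs short survival grouping at ``cutoff_days``.

    Long: observed survival beyond the cutoff (event or censored at or after
    it).  Short: death before the cutoff.  Censored before the cutoff is
    uninformative and excluded; the excluded ids are returned for reporting.
    """
    long_mask = cohort["os_days"] >= cutoff_days
    short_mask = (cohort["os_days"] < cutoff_days) & cohort["event"].astype(bool)
    excluded = list(cohort.index[~long_mask & ~short_mask])
    labels = pd.Series(
        np.where(long_mask, "long", "short"),
        index=cohort.index,
    )[long_mask | short_mask]
    return labels, excluded


def _two_levels(groups: pd.Series):
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    return levels
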