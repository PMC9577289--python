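"""IHC cell-ratio statistics with normality-routed group comparisons.

Immune-cell ratios are plain quotients of quantitative-pathology densities:
(positive cells/mm²) / (CD45+ cells/mm²).  Group comparisons follow a
Shapiro–Wilk routing rule: when every group looks normal (all Shapiro p >
alpha) the parametric branch is used (Student's t for two groups, one-way
ANOVA beyond), otherwise the rank-based branch (Mann–Whitney / Wilcoxon
rank-sum, or Kruskal–Wallis).  Small groups (n < 3) force the
non-parametric branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

EXACT_MANNWHITNEY_MAX_N = 20


@dataclass
class GroupTestResult:
    """Routed two-/multi-group comparison outcome."""

    test_used: str                 # t | wilcoxon | anova | kruskal_wallis
    statistic: float
    p: float
    normality_ps: dict = field(default_factory=dict)


def ihc_ratio(density: pd.Series | float, density_cd45: pd.Series | float):
    """Marker density over CD45 density; undefined (NaN) where CD45 is 0."""
    marker = np.asarray(density, dtype=float)
    cd45 = np.asarray(density_cd45, dtype=float)
    undefined = cd45 == 0
    if undefined.any():
        warnings.warn("CD45 density 0: ratio undefined for some samples",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(undefined, np.nan, marker / np.where(undefined, 1.0, cd45))
    if isinstance(density, pd.Series):
        return pd.Series(out, index=density.index)
    return float(out) if out.ndim == 0 else out


def ihc_ratio_table(ihc: pd.DataFrame) -> pd.DataFrame:
    """All marker/CD45 ratios for an IHC density table."""
    markers = [c for c in ihc.columns if c != "CD45"]
    return pd.DataFrame(
        {m: ihc_ratio(ihc[m], ihc["CD45"]) for m in markers}, index=ihc.index
    )


def compare_groups(values, group_labels, alpha_normal: float = 0.05
                   ) -> GroupTestResult:
    """Shapiro-routed comparison of a variable across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    level_names = pd.unique(labels)
    groups = [values[labels == lev] for lev in level_names]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    small = [lev for lev, g in zip(level_names, groups) if len(g) < 3]
    normality: dict = {}
    if small:
        warnings.warn(
            f"groups with n < 3 ({list(small)}): forcing non-parametric branch",
            stacklevel=2,
        )
        parametric = False
    else:
        for lev, g in zip(level_names, groups):
            if np.ptp(g) == 0:
                normality[lev] = 0.0  # degenerate: cannot look normal
            else:
                normality[lev] = float(stats.shapiro(g).pvalue)
        parametric = all(p > alpha_normal for p in normality.values())

    if len(groups) == 2:
        if parametric:
            res = stats.ttest_ind(groups[0], groups[1])
            test = "t"
        else:
            method = "exact" if (max(map(len, groups)) <= EXACT_MANNWHITNEY_MAX_N
                                 and not _has_ties(values)) else "asymptotic"
            res = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided", method=method)
            test = "wilcoxon"
    else:
        if parametric:
            res = stats.f_oneway(*groups)
            test = "anova"
        else:
            res = stats.kruskal(*groups)
            test = "kruskal_wallis"
    return GroupTestResult(
        test_used=test,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        normality_ps=normality,
    )


def compare_table(ratios: pd.DataFrame, group_labels: pd.Series,
                  alpha_normal: float = 0.05, fdr_adjust: bool = False
                  ) -> pd.DataFrame:
    """Routed comparisons for every variable (column) of a ratio table.

    ``fdr_adjust`` optionally runs a BH pass over the declared comparison
    family (off by default).
    """
    common = ratios.index.intersection(group_labels.index)
    rows = []
    for col in ratios.columns:
        vals = ratios.loc[common, col]
        ok = vals.notna()
        res = compare_groups(vals[ok], group_labels.loc[common][ok],
                             alpha_normal=alpha_normal)
        rows.append(
            {
                "variable": col,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p,
                "normality_ps": ";".join(f"{k}={v:.4g}"
                                         for k, v in res.normality_ps.items()),
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    if fdr_adjust:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)
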