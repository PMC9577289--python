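"""Kaplan–Meier curves, log-rank tests and Cox proportional-hazards models.

Estimation is delegated to ``lifelines`` (product-limit estimator, O−E /
hypergeometric-variance log-rank, Efron-tie partial likelihood); this module
fixes the cohort-specific covariate codings and reporting conventions:

* age dichotomized strictly above 70 years;
* PD-L1 tumour positivity dichotomized low 0–49% vs high ≥50%;
* the four immune clusters entered as an ordinal trend covariate
  (C1+C2 → 0, C3 → 1, C4 → 2), one hazard ratio per step;
* Wald 95% CIs ``exp(beta ± 1.96 se)`` and Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ConvergenceError

AGE_CUTOFF_YEARS = 70.0       # high = strictly above
PDL1_CUTOFF_PERCENT = 50.0    # high = at or above
CLUSTER_ORDINAL = {"C1": 0, "C2": 0, "C3": 1, "C4": 2}


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk/death tallies and median OS."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    median_os: float | None


@dataclass
class CoxFit:
    """Cox PH fit: per-covariate beta, HR, Wald CI/p, plus fit summary."""

    table: pd.DataFrame   # index covariate; beta, hr, ci_low, ci_high, wald_p
    loglik: float
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Median OS is the smallest observed time with survival <= 0.5 (None if
    the curve never reaches 0.5).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table[kmf.event_table.index > 0]
    event_times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    med = kmf.median_survival_time_
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
        deaths=tab["observed"].to_numpy(),
        median_os=None if np.isinf(med) else float(med),
    )


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Chi-square log-rank test across >= 2 groups; returns (statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if not events.any():
        raise ValueError("need >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(data: pd.DataFrame, covariates, duration_col: str = "os_days",
            event_col: str = "event") -> CoxFit:
    """Cox PH regression with Efron tie handling via Newton iterations.

    ``data`` must hold the duration, event flag and numeric covariate
    columns; rows with missing values in any used column are dropped
    (listwise deletion happens only here).  A rank-deficient covariate
    matrix raises ``ValueError``; non-convergence raises
    ``ConvergenceError``.
    """
    covariates = list(covariates)
    cols = [duration_col, event_col] + covariates
    df = data[cols].dropna().copy()
    df[event_col] = df[event_col].astype(bool)
    if not df[event_col].any():
        raise ValueError("need >= 1 event")
    X = df[covariates].to_numpy(dtype=float)
    centred = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centred) < len(covariates):
        raise ValueError("collinear covariates: covariate matrix is rank deficient")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    beta = cph.params_
    se = cph.standard_errors_
    table = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "wald_p": cph.summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxFit(
        table=table.loc[covariates],
        loglik=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=int(df[event_col].sum()),
    )


def code_covariates(cohort: pd.DataFrame,
                    clusters: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministic covariate codings for survival modelling.

    Returns a DataFrame (indexed like ``cohort``) with ``os_days``,
    ``event`` and coded covariates: ``age_high`` (age > 70), ``pdl1_high``
    (PD-L1 >= 50%), ``sex_male``, optional ``metastasis``/``chemo`` passed
    through, and ``cluster_ordinal`` (C1+C2=0, C3=1, C4=2) when ``clusters``
    is given.  Samples without a cluster assignment are dropped with a
    report when clusters are requested.
    """
    out = pd.DataFrame(index=cohort.index)
    out["os_days"] = cohort["os_days"]
    out["event"] = cohort["event"].astype(bool)
    out["age_high"] = (cohort["age_years"] > AGE_CUTOFF_YEARS).astype(float)
    out["pdl1_high"] = (cohort["pdl1_percent"] >= PDL1_CUTOFF_PERCENT).astype(float)
    if "sex" in cohort.columns:
        out["sex_male"] = (cohort["sex"] == "male").astype(float)
    for optional in ("metastasis", "chemo"):
        if optional in cohort.columns:
            out[optional] = pd.to_numeric(cohort[optional], errors="coerce")
    if clusters is not None:
        labels = clusters["cluster"] if "cluster" in clusters else clusters
        ordinal = labels.map(CLUSTER_ORDINAL)
        out = out.join(ordinal.rename("cluster_ordinal"), how="left")
        missing = out.index[out["cluster_ordinal"].isna()]
        if len(missing):
            warnings.warn(
                f"dropped {len(missing)} samples without cluster assignment: "
                f"{list(missing)[:5]}...",
                stacklevel=2,
            )
            out = out.dropna(subset=["cluster_ordinal"])
    return out


def cox_table(coded: pd.DataFrame, univariable, multivariable) -> pd.DataFrame:
    """Univariable + multivariable Cox summary in one reporting table."""
    rows = []
    for cov in univariable:
        fit = cox_fit(coded, [cov])
        row = fit.table.loc[cov]
        rows.append({"covariate": cov, "model": "univariable", **row.to_dict()})
    if multivariable:
        fit = cox_fit(coded, list(multivariable))
        for cov in multivariable:
            row = fit.table.loc[cov]
            rows.append({"covariate": cov, "model": "multivariable", **row.to_dict()})
    return pd.DataFrame(rows)
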