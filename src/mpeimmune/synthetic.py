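"""Synthetic MPE cohort generator.

Emulates the statistical structure the analysis assumes so that every stage
is testable without patient data and parameter recovery is quantifiable:

* four immune archetypes over the clustering panel — cluster-A (adaptive +
  cytotoxic) genes elevated in hot patients (C1/C2), cluster-B (innate)
  genes elevated in innate+ patients (C1/C4);
* immunomodulators co-elevated with the hot programme except for a small
  cold-elevated set (CD274, TNFRSF9, VEGFA, CD276, KIR2DL3); RIG-I-like /
  type I interferon pathway genes elevated in hot patients;
* negative-binomial counts with lognormal sample-depth variation, a fixed
  positive-control geometric ladder under a per-sample platform factor,
  Poisson negative controls, housekeepers scaling with depth only;
* exponential proportional-hazards survival with covariate effects
  (age > 70, ordinal patient cluster, PD-L1 high) and independent uniform
  administrative censoring;
* PD-L1 scores and IHC densities consistent with the archetypes.

The baseline hazard is calibrated by root-finding so the marginal median
overall survival matches ``target_median_os`` (107 days), and the censoring
window is solved for the requested censoring fraction.  Generation is
bit-reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .io import (ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE, RawCountMatrix,
                 read_clustering_panel, read_marker_panel, read_modulator_list)

CLUSTERS = ("C1", "C2", "C3", "C4")
ORDINAL = {"C1": 0, "C2": 0, "C3": 1, "C4": 2}
HOT_CLUSTERS = ("C1", "C2")
INNATE_CLUSTERS = ("C1", "C4")

# Default survival log-coefficients: ln of the multivariable hazard ratios
# the cohort analysis is expected to recover (age>70: 2.513, per cluster
# step: 1.648, PD-L1 high: 3.316).
DEFAULT_COEFFICIENTS = {
    "age_high": float(np.log(2.513)),
    "cluster_ordinal": float(np.log(1.648)),
    "pdl1_high": float(np.log(3.316)),
}

HOUSEKEEPING_GENES = [
    "ACTB", "GAPDH", "B2M", "TUBB", "GUSB", "HPRT1", "PGK1", "PPIA",
    "RPL19", "RPLP0", "SDHA", "TBP", "TFRC", "UBC", "YWHAZ", "POLR1B",
    "ABCF1", "ALAS1", "EEF1G", "OAZ1",
]

FILLER_GENES = [
    "AKT1", "AKT2", "BRAF", "EGFR", "KRAS", "TP53", "MYC", "PTEN", "RB1",
    "STAT1", "STAT3", "JAK1", "JAK2", "MAPK1", "MAPK3", "PIK3CA", "NFKB1",
    "RELA", "SMAD4", "TGFB1", "IL6", "IL10", "TNF", "CCL2", "CCL5",
    "CXCL12", "MMP9", "VIM", "CDH1", "EPCAM", "KRT19", "MKI67", "CCND1",
    "CDK4", "CDKN2A", "BCL2", "BAX", "CASP3", "HIF1A", "VHL",
]

# nCounter-style positive-control ladder (counts at unit platform factor)
POSITIVE_LADDER = (12000.0, 3000.0, 750.0, 190.0, 48.0, 12.0)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 83
    cluster_proportions: tuple = (0.25, 0.25, 0.30, 0.20)  # C1..C4
    adaptive_shift: float = 2.0       # log2 offset of A genes in hot patients
    innate_shift: float = 2.0         # log2 offset of B genes in innate+ patients
    modulator_shift: float = 1.0      # log2 offset of modulator/pathway genes
    cytotoxic_extra_shift: float = 0.5  # extra hot offset of CD8/cytotoxic genes
    nb_dispersion: float = 0.2
    n_positive: int = 6
    n_negative: int = 8
    n_housekeeping: int = 20
    depth_sigma: float = 0.25         # lognormal sd of sample input
    platform_sigma: float = 0.15      # lognormal sd of the lane/platform factor
    background_mean: float = 8.0      # negative-control Poisson mean
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    baseline_hazard: float | None = None   # per day; None = calibrate
    target_median_os: float = 107.0        # days
    censor_rate: float = 0.30
    pdl1_high_prob: float = 0.20
    age_mean: float = 70.0
    age_sd: float = 12.0
    age_range: tuple = (29.0, 93.0)
    male_prob: float = 0.54
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9 or \
                any(p < 0 for p in self.cluster_proportions):
            raise ConfigError("cluster_proportions must be non-negative and sum to 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.n_patients < 4:
            raise ConfigError("need at least 4 patients")
        if min(self.n_positive, self.n_negative) < 1 or self.n_housekeeping < 3:
            raise ConfigError("need >= 1 positive/negative and >= 3 housekeeping probes")


@dataclass
class SyntheticCohort:
    """Generated tables plus the generating truth."""

    raw: RawCountMatrix
    cohort: pd.DataFrame
    truth: pd.DataFrame              # per-sample temperature/innate/cluster
    ihc: pd.DataFrame
    config: GeneratorConfig

    def truth_report(self) -> dict:
        cfg = asdict(self.config)
        cfg["cluster_proportions"] = list(cfg["cluster_proportions"])
        cfg["age_range"] = list(cfg["age_range"])
        return {
            "config": cfg,
            "baseline_hazard": calibrated_baseline_hazard(self.config),
            "labels": {s: row["cluster"] for s, row in self.truth.iterrows()},
        }


def sample_nb(rng: np.random.Generator, mean, dispersion: float):
    """Gamma–Poisson draw: NB with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


# ---------------------------------------------------------------------------
# Survival machinery (shared with the lean recovery-experiment path)
# ---------------------------------------------------------------------------

def _covariate_mixture(config: GeneratorConfig):
    """(weight, multiplier) pairs over the joint covariate distribution."""
    p = config.cluster_proportions
    ord_probs = {0: p[0] + p[1], 1: p[2], 2: p[3]}
    beta = config.coefficients
    out = []
    for age in (0, 1):
        for ordv, pw in ord_probs.items():
            for pdl1 in (0, 1):
                w = 0.5 * pw * (config.pdl1_high_prob if pdl1 else 1 - config.pdl1_high_prob)
                m = np.exp(beta.get("age_high", 0.0) * age
                           + beta.get("cluster_ordinal", 0.0) * ordv
                           + beta.get("pdl1_high", 0.0) * pdl1)
                out.append((w, m))
    return out


def calibrated_baseline_hazard(config: GeneratorConfig) -> float:
    """Baseline hazard giving marginal median OS = ``target_median_os``."""
    if config.baseline_hazard is not None:
        return config.baseline_hazard
    mix = _covariate_mixture(config)

    def marginal_surv(u: float) -> float:
        return sum(w * np.exp(-m * u) for w, m in mix) - 0.5

    u = brentq(marginal_surv, 1e-9, 50.0)
    return u / config.target_median_os


def _censoring_window(rates: np.ndarray, censor_rate: float) -> float:
    """Uniform(0, w) administrative window giving the target censor fraction.

    P(censored | rate λ) under C ~ U(0, w) is (1 − e^{−λw}) / (λw); the
    window solves the average over the cohort's subject-level rates.
    """
    if censor_rate <= 0:
        return np.inf

    def mean_censored(w: float) -> float:
        lw = rates * w
        return float(np.mean((1.0 - np.exp(-lw)) / lw)) - censor_rate

    return brentq(mean_censored, 1e-9, 1e9)


def simulate_survival(rng: np.random.Generator, covariates: pd.DataFrame,
                      config: GeneratorConfig) -> pd.DataFrame:
    """Exponential PH survival times with uniform administrative censoring."""
    lam0 = calibrated_baseline_hazard(config)
    lp = np.zeros(len(covariates))
    for name, beta in config.coefficients.items():
        if name in covariates:
            lp += beta * covariates[name].to_numpy(dtype=float)
    rates = lam0 * np.exp(lp)
    t = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        w = _censoring_window(rates, config.censor_rate)
        c = rng.uniform(0.0, w, size=len(t))
        os_days = np.minimum(t, c)
        event = t <= c
    else:
        os_days, event = t, np.ones(len(t), dtype=bool)
    out = covariates.copy()
    out["os_days"] = os_days
    out["event"] = event
    return out


def simulate_ph_cohort(n: int, coefficients: dict, seed: int,
                       censor_rate: float = 0.30,
                       pdl1_high_prob: float = 0.20) -> pd.DataFrame:
    """Lean PH recovery experiment: independent covariates, continuous times.

    Covariates: ``age_high`` ~ Bern(0.5), ``cluster_ordinal`` ~ Unif{0,1,2},
    ``pdl1_high`` ~ Bern(``pdl1_high_prob``), mutually independent.  Only
    the coefficients named in ``coefficients`` act on the hazard.  Returns a
    DataFrame ready for Cox fitting.
    """
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {
            "age_high": rng.binomial(1, 0.5, n).astype(float),
            "cluster_ordinal": rng.integers(0, 3, n).astype(float),
            "pdl1_high": rng.binomial(1, pdl1_high_prob, n).astype(float),
        }
    )
    cfg = GeneratorConfig(
        n_patients=max(n, 4),
        cluster_proportions=(1 / 6, 1 / 6, 1 / 3, 1 / 3),  # ordinal ~ Unif{0,1,2}
        coefficients={k: float(v) for k, v in coefficients.items()},
        censor_rate=censor_rate,
        pdl1_high_prob=pdl1_high_prob,
    )
    cfg.validate()
    return simulate_survival(rng, cov, cfg)


# ---------------------------------------------------------------------------
# Full cohort generation
# ---------------------------------------------------------------------------

def _gene_plan(config: GeneratorConfig, rng: np.random.Generator):
    """Per-gene baseline log2 means and per-archetype log2 offsets."""
    panel = read_clustering_panel()
    mods = read_modulator_list()
    genes_a = panel["cluster_A"]
    genes_b = panel["cluster_B"]
    panel_set = set(genes_a) | set(genes_b)
    modulators = [g for g in mods["genes"] if g not in panel_set]
    cold_set = set(mods["cold_elevated"])
    pathway = [g for g in mods["pathway_genes"] if g not in panel_set]

    endo = (list(genes_a) + list(genes_b) + modulators + pathway
            + ["PTPRC"] + FILLER_GENES)
    baseline = pd.Series(rng.uniform(5.0, 8.0, len(endo)), index=endo)
    baseline["PTPRC"] = 7.0

    # log2 offsets per gene for (hot, innate+) indicators
    hot_off = pd.Series(0.0, index=endo)
    innate_off = pd.Series(0.0, index=endo)
    hot_off[genes_a] = config.adaptive_shift
    innate_off[genes_b] = config.innate_shift
    # the hot phenotype is specifically cytotoxic-enriched: CD8 and shared
    # cytotoxic genes rise above the general adaptive programme
    marker_panel = read_marker_panel()
    cytotoxic = [g for g in (marker_panel.cell_types.get("CD8 T cells", [])
                             + marker_panel.cytotoxic_genes) if g in hot_off.index]
    hot_off[cytotoxic] += config.cytotoxic_extra_shift
    for g in modulators:
        if g in cold_set:
            hot_off[g] = -config.modulator_shift   # elevated in cold clusters
        else:
            hot_off[g] = config.modulator_shift
    hot_off[pathway] = config.modulator_shift
    # the pan-leukocyte gene tracks total immune content; its coupling must
    # dominate the per-gene NB noise so lymphocyte scores correlate with it
    hot_off["PTPRC"] = 1.8
    innate_off["PTPRC"] = 1.0
    return baseline, hot_off, innate_off


def generate(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config`` (seeded)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    samples = [f"MPE{idx + 1:03d}" for idx in range(n)]

    clusters = rng.choice(CLUSTERS, size=n, p=config.cluster_proportions)
    hot = np.isin(clusters, HOT_CLUSTERS).astype(float)
    innate = np.isin(clusters, INNATE_CLUSTERS).astype(float)
    truth = pd.DataFrame(
        {
            "temperature": np.where(hot == 1, "hot", "cold"),
            "innate": np.where(innate == 1, "plus", "minus"),
            "cluster": clusters,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # ---- counts ---------------------------------------------------------
    baseline, hot_off, innate_off = _gene_plan(config, rng)
    log2_mean = (baseline.to_numpy()[None, :]
                 + np.outer(hot, hot_off.to_numpy())
                 + np.outer(innate, innate_off.to_numpy()))
    depth = np.exp(rng.normal(0.0, config.depth_sigma, n))
    platform = np.exp(rng.normal(0.0, config.platform_sigma, n))
    endo_mean = (2.0 ** log2_mean) * depth[:, None]
    endo_counts = sample_nb(rng, endo_mean, config.nb_dispersion)

    hk_genes = HOUSEKEEPING_GENES[: config.n_housekeeping]
    hk_base = 2.0 ** rng.uniform(7.0, 10.0, len(hk_genes))
    hk_mean = hk_base[None, :] * depth[:, None]
    hk_counts = sample_nb(rng, hk_mean, config.nb_dispersion / 4.0)

    ladder = np.resize(np.asarray(POSITIVE_LADDER), config.n_positive)
    pos_counts = rng.poisson(ladder[None, :] * platform[:, None])
    neg_counts = rng.poisson(config.background_mean,
                             size=(n, config.n_negative))

    endo_genes = list(baseline.index)
    probe_ids = (endo_genes + hk_genes
                 + [f"POS_{c}" for c in range(1, config.n_positive + 1)]
                 + [f"NEG_{c}" for c in range(1, config.n_negative + 1)])
    annotation = pd.DataFrame(
        {
            "gene_symbol": endo_genes + hk_genes
            + [""] * (config.n_positive + config.n_negative),
            "probe_class": [ENDOGENOUS] * len(endo_genes)
            + [HOUSEKEEPING] * len(hk_genes)
            + [POSITIVE] * config.n_positive
            + [NEGATIVE] * config.n_negative,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    counts = pd.DataFrame(
        np.hstack([endo_counts, hk_counts, pos_counts, neg_counts]).astype(np.int64),
        index=pd.Index(samples, name="sample_id"),
        columns=annotation.index,
    )
    raw = RawCountMatrix(counts=counts, annotation=annotation)

    # ---- clinical -------------------------------------------------------
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    sex = np.where(rng.random(n) < config.male_prob, "male", "female")
    pdl1_high = rng.binomial(1, config.pdl1_high_prob, n)
    pdl1 = np.where(pdl1_high == 1, rng.uniform(50.0, 100.0, n),
                    rng.uniform(0.0, 49.0, n))
    covariates = pd.DataFrame(
        {
            "age_high": (age > 70.0).astype(float),
            "cluster_ordinal": [float(ORDINAL[c]) for c in clusters],
            "pdl1_high": pdl1_high.astype(float),
        },
        index=truth.index,
    )
    surv = simulate_survival(rng, covariates, config)
    os_days = np.maximum(np.ceil(surv["os_days"].to_numpy()), 1.0)

    cohort = pd.DataFrame(
        {
            "os_days": os_days,
            "event": surv["event"].to_numpy(),
            "age_years": np.round(age, 1),
            "sex": sex,
            "pdl1_percent": np.round(pdl1, 1),
            "metastasis": _with_missing(rng.binomial(1, 0.54, n), 0.37, rng),
            "chemo": _with_missing(rng.binomial(1, 0.39, n), 0.33, rng),
        },
        index=truth.index,
    )

    # ---- IHC densities --------------------------------------------------
    cd45 = 150.0 * 2.0 ** (1.3 * hot + 0.7 * innate) \
        * np.exp(rng.normal(0.0, 0.3, n))
    frac = {
        "CD3": 0.30 + 0.15 * hot,
        "CD4": 0.18 + 0.08 * hot,
        "CD8": 0.08 + 0.17 * hot,
        "CD20": 0.05 + 0.10 * hot,
        "CD68": 0.10 + 0.10 * (1 - hot) + 0.15 * innate,
        "MPO": 0.08 + 0.08 * (1 - hot) + 0.12 * innate,
    }
    ihc = pd.DataFrame(
        {m: cd45 * f * np.exp(rng.normal(0.0, 0.2, n)) for m, f in frac.items()},
        index=truth.index,
    )
    ihc["CD45"] = cd45
    ihc = ihc.round(1)

    return SyntheticCohort(raw=raw, cohort=cohort, truth=truth, ihc=ihc,
                           config=config)


def _with_missing(values: np.ndarray, missing_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    out = values.astype(float)
    out[rng.random(len(out)) < missing_rate] = np.nan
    return out


def write_truth_report(cohort: SyntheticCohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.truth_report(), fh, indent=2, sort_keys=True)
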