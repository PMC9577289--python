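"""End-to-end orchestration: normalize → score → cluster → DE → survival →
correlations → IHC statistics, with provenance-stamped outputs and a
collated JSON report.

Every stage writes its table with a ``#`` provenance header (package
version, stage, parameters, SHA-256 of the stage inputs) so a run can be
audited file by file; the final report gathers cluster sizes, median OS per
cluster, log-rank p-values, the Cox table, DE summary counts and the TILs
gate membership.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import (ENDOGENOUS, RawCountMatrix, read_cohort_table, read_count_table,
                 read_clustering_panel, read_ihc_table, read_marker_panel,
                 read_modulator_list)
from .normalization import default_qc_threshold, normalize
from .scoring import score_pipeline
from .clustering import assign_patients, partition_genes
from .diffexpr import nb_wald_test, survival_groups
from .survival import code_covariates, cox_table, km_estimate, logrank_test
from .correlation import cluster_mean_profiles, pearson_matrix
from .ihc import compare_table, ihc_ratio_table

log = logging.getLogger("mpeimmune")


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """Input paths and per-stage parameter blocks."""

    counts: str | None = None
    clinical: str | None = None
    ihc: str | None = None
    marker_panel: str | None = None       # None = packaged default
    clustering_panel: str | None = None
    modulators: str | None = None
    out_dir: str = "mpeimmune_out"
    seed: int = 0
    normalization: dict = field(default_factory=dict)  # background_method, pseudocount, housekeeping_genes
    scoring: dict = field(default_factory=dict)        # qc_threshold, r_min
    clustering: dict = field(default_factory=dict)     # variant, patient_split
    de: dict = field(default_factory=dict)             # survival_cutoff_days
    survival: dict = field(default_factory=dict)       # multivariable covariates
    correlation: dict = field(default_factory=dict)    # fdr_threshold
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.counts is None or self.clinical is None:
            raise ConfigError("config must name counts and clinical input files")
        for name in ("counts", "clinical", "ihc", "marker_panel",
                     "clustering_panel", "modulators"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, inputs: dict,
               params: dict | None = None, index: bool = True) -> None:
    header = (
        f"# mpeimmune {__version__}; stage={stage}; "
        f"inputs={json.dumps(inputs, sort_keys=True)}; "
        f"params={json.dumps(params or {}, sort_keys=True, default=str)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the collated report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}
    hashes = {"counts": _sha256(config.counts), "clinical": _sha256(config.clinical)}
    if config.ihc:
        hashes["ihc"] = _sha256(config.ihc)

    stage = "load"
    try:
        raw = read_count_table(config.counts)
        cohort = read_cohort_table(config.clinical)
        ihc = read_ihc_table(config.ihc) if config.ihc else None
        marker_panel = read_marker_panel(config.marker_panel)
        clustering_panel = read_clustering_panel(config.clustering_panel)
        modulators = read_modulator_list(config.modulators)

        stage = "normalize"
        ncfg = config.normalization
        expr = normalize(
            raw,
            background_method=ncfg.get("background_method", "mean"),
            pseudocount=float(ncfg.get("pseudocount", 1.0)),
            housekeeping_genes=ncfg.get("housekeeping_genes"),
        )
        _write_tsv(expr.values, out / "expression.tsv", stage, hashes, ncfg)
        _write_tsv(expr.factors.to_frame(), out / "normalization_factors.tsv",
                   stage, hashes, ncfg)
        log.info("normalized %d samples x %d genes", *expr.values.shape)

        stage = "score"
        scfg = config.scoring
        qc = scfg.get("qc_threshold")
        qc = default_qc_threshold(raw, float(ncfg.get("pseudocount", 1.0))) \
            if qc is None else float(qc)
        scores = score_pipeline(expr, marker_panel, qc_threshold=qc,
                                r_min=float(scfg.get("r_min", 0.6)))
        score_out = scores.scores.copy()
        if scores.tils is not None:
            score_out["TILs"] = scores.tils
            for cell in scores.scores.columns:
                score_out[f"{cell}/TILs"] = scores.relative[cell]
        _write_tsv(score_out, out / "cell_scores.tsv", stage, hashes,
                   {"qc_threshold": qc, **scfg})
        with open(out / "tils_gate.json", "w") as fh:
            json.dump({"members": scores.tils_members,
                       "unscorable": scores.unscorable}, fh, indent=2)
        report["tils_gate"] = scores.tils_members

        stage = "cluster"
        ccfg = config.clustering
        panel_genes = clustering_panel["cluster_A"] + clustering_panel["cluster_B"]
        seeds = [g for cell in clustering_panel["seed_cell_types"]
                 for g in marker_panel.cell_types.get(cell, [])]
        partition = partition_genes(expr, panel_genes, seeds,
                                    variant=ccfg.get("variant", "ward_d"))
        assignment = assign_patients(expr, partition,
                                     variant=ccfg.get("variant", "ward_d"),
                                     method=ccfg.get("patient_split", "dendrogram"))
        _write_tsv(assignment, out / "cluster_assignments.tsv", stage, hashes, ccfg)
        gene_part = pd.DataFrame(
            {"gene": partition.cluster_A_genes + partition.cluster_B_genes,
             "block": ["A"] * len(partition.cluster_A_genes)
             + ["B"] * len(partition.cluster_B_genes)}
        )
        _write_tsv(gene_part, out / "gene_partition.tsv", stage, hashes,
                   index=False)
        report["cluster_sizes"] = assignment["cluster"].value_counts().to_dict()

        stage = "de"
        dcfg = config.de
        common = raw.counts.index.intersection(cohort.index)
        endo = raw.counts_of_class(ENDOGENOUS).loc[common]
        pdl1_groups = pd.Series(
            np.where(cohort.loc[common, "pdl1_percent"] >= 50.0, "high", "low"),
            index=common,
        )
        de_pdl1 = nb_wald_test(endo, pdl1_groups, levels=["low", "high"])
        _write_tsv(de_pdl1, out / "de_pdl1.tsv", stage, hashes, dcfg)
        surv_labels, excluded = survival_groups(
            cohort.loc[common], cutoff_days=float(dcfg.get("survival_cutoff_days", 90.0)))
        de_surv = nb_wald_test(endo.loc[surv_labels.index], surv_labels,
                               levels=["short", "long"])
        _write_tsv(de_surv, out / "de_survival.tsv", stage, hashes,
                   {"excluded_censored_before_cutoff": excluded, **dcfg})
        report["de"] = {
            "pdl1_significant": int(de_pdl1["significant"].sum()),
            "survival_significant": int(de_surv["significant"].sum()),
            "survival_excluded": len(excluded),
        }

        stage = "survival"
        vcfg = config.survival
        coded = code_covariates(cohort, assignment)
        km_rows = []
        medos = {}
        for cluster, sub in coded.groupby(assignment["cluster"]):
            curve = km_estimate(sub["os_days"], sub["event"])
            medos[cluster] = curve.median_os
            km_rows.append(pd.DataFrame(
                {"group": cluster, "time": curve.event_times,
                 "survival": curve.survival, "at_risk": curve.at_risk,
                 "deaths": curve.deaths}))
        _write_tsv(pd.concat(km_rows), out / "km_curves.tsv", stage, hashes,
                   index=False)
        temp = assignment.loc[coded.index, "temperature"]
        logrank = {
            "hot_vs_cold": logrank_test(coded["os_days"], coded["event"], temp),
            "clusters": logrank_test(coded["os_days"], coded["event"],
                                     assignment.loc[coded.index, "cluster"]),
        }
        with open(out / "logrank.json", "w") as fh:
            json.dump(logrank, fh, indent=2)
        uni = vcfg.get("univariable",
                       ["age_high", "sex_male", "metastasis", "chemo",
                        "cluster_ordinal", "pdl1_high"])
        uni = [c for c in uni if c in coded.columns]
        multi = vcfg.get("multivariable", ["age_high", "cluster_ordinal", "pdl1_high"])
        cox = cox_table(coded, univariable=uni, multivariable=multi)
        _write_tsv(cox, out / "cox_table.tsv", stage, hashes, vcfg, index=False)
        report["median_os_per_cluster"] = medos
        report["logrank_p"] = {k: v[1] for k, v in logrank.items()}
        report["cox_table"] = cox.to_dict(orient="records")

        stage = "correlate"
        rcfg = config.correlation
        corr = pearson_matrix(expr, genes=list(modulators["genes"]),
                              fdr_threshold=float(rcfg.get("fdr_threshold", 0.01)))
        _write_tsv(corr.long_format(), out / "modulator_correlation.tsv",
                   stage, hashes, rcfg, index=False)
        ordered = corr.r.loc[corr.display_order, corr.display_order]
        _write_tsv(ordered, out / "modulator_correlation_ordered.tsv",
                   stage, hashes, rcfg)
        profile_genes = list(modulators["genes"]) + modulators["pathway_genes"]
        profiles = cluster_mean_profiles(expr, assignment, genes=profile_genes)
        _write_tsv(profiles, out / "cluster_profiles.tsv", stage, hashes, rcfg)

        if ihc is not None:
            stage = "ihc"
            ratios = ihc_ratio_table(ihc)
            _write_tsv(ratios, out / "ihc_ratios.tsv", stage, hashes)
            comp = compare_table(ratios, assignment["temperature"])
            _write_tsv(comp, out / "ihc_comparisons.tsv", stage, hashes)
            report["ihc_p"] = comp["p"].to_dict()

        if config.plots:
            stage = "plots"
            _heatmaps(expr, panel_genes, assignment, corr, out)
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s",
                  stage, out)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("pipeline complete; report at %s", out / "report.json")
    return report


def _heatmaps(expr, panel_genes, assignment, corr, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .clustering import zscore_genes

    present = [g for g in panel_genes if g in expr.values.columns]
    z = zscore_genes(expr.values[present])
    order = assignment.sort_values(["cluster"]).index
    fig, ax = plt.subplots(figsize=(8, 10))
    ax.imshow(z.loc[order].T, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xlabel("patients (by cluster)")
    ax.set_ylabel("panel genes")
    fig.savefig(out / "panel_heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 8))
    ordered = corr.r.loc[corr.display_order, corr.display_order]
    masked = ordered.where(~corr.mask.loc[corr.display_order, corr.display_order], 0.0)
    ax.imshow(masked, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_title("immunomodulator correlation (FDR-masked)")
    fig.savefig(out / "modulator_correlation.png", dpi=120)
    plt.close(fig)
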