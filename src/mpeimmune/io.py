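"""Reading, writing and validation of nCounter-style tables.

The data model every downstream stage assumes:

* :class:`RawCountMatrix` — samples x probes of non-negative integer counts
  with per-probe class annotation (endogenous / positive control / negative
  control / housekeeping);
* a clinical cohort table (sample id, overall survival in days, event flag,
  age, sex, PD-L1 % tumour-cell positivity, optional covariates);
* an IHC density table (positive cells per mm² per marker, plus CD45);
* a :class:`MarkerPanel` mapping immune cell types to marker genes.

Count files may be probes-as-rows (columns ``probe_id, gene_symbol,
probe_class, <sample>...``) or the transposed orientation; the layout is
detected from the header keyword ``probe_class``.  Lines starting with ``#``
are treated as comments in every format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError

# Canonical probe classes and accepted (case-insensitive) synonyms.
ENDOGENOUS = "endogenous"
POSITIVE = "positive"
NEGATIVE = "negative"
HOUSEKEEPING = "housekeeping"
PROBE_CLASSES = (ENDOGENOUS, POSITIVE, NEGATIVE, HOUSEKEEPING)

_CLASS_SYNONYMS = {
    "endogenous": ENDOGENOUS,
    "endogenous1": ENDOGENOUS,
    "positive": POSITIVE,
    "positive control": POSITIVE,
    "pos": POSITIVE,
    "negative": NEGATIVE,
    "negative control": NEGATIVE,
    "neg": NEGATIVE,
    "housekeeping": HOUSEKEEPING,
    "housekeeper": HOUSEKEEPING,
    "hk": HOUSEKEEPING,
}

REQUIRED_COHORT_COLUMNS = ("sample_id", "os_days", "event", "age_years", "pdl1_percent")

IHC_MARKERS = ("CD3", "CD4", "CD8", "CD20", "CD68", "MPO", "CD45")


def _canonical_class(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _CLASS_SYNONYMS:
        raise FormatError(f"unknown probe class {value!r}")
    return _CLASS_SYNONYMS[key]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Identity and class of a single probe."""

    probe_id: str
    gene_symbol: str
    probe_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_class", _canonical_class(self.probe_class))
        if self.probe_class in (ENDOGENOUS, HOUSEKEEPING) and not self.gene_symbol:
            raise IntegrityError(
                f"probe {self.probe_id}: {self.probe_class} probes need a gene symbol"
            )


@dataclass
class RawCountMatrix:
    """Samples x probes of raw digital counts with probe-class annotation.

    ``counts`` is indexed by sample id with one column per probe id;
    ``annotation`` is indexed by probe id with columns ``gene_symbol`` and
    ``probe_class``.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = self.annotation.copy()
        self.annotation["probe_class"] = [
            _canonical_class(c) for c in self.annotation["probe_class"]
        ]
        self.annotation = self.annotation.rename_axis("probe_id")
        self.counts = self.counts.rename_axis("sample_id", axis=0) \
                                 .rename_axis("probe_id", axis=1)
        self.validate()

    def validate(self) -> None:
        ann = self.annotation
        if list(self.counts.columns) != list(ann.index):
            raise IntegrityError("counts columns and annotation index disagree")
        if ann.index.duplicated().any():
            dup = ann.index[ann.index.duplicated()][0]
            raise IntegrityError(f"duplicate probe id {dup!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise IntegrityError(f"duplicate sample id {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            s, p = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[s]!r}, "
                f"probe {self.counts.columns[p]!r}"
            )
        bad = ann["probe_class"].isin(PROBE_CLASSES)
        if not bad.all():
            raise FormatError(f"unknown probe class for probe {ann.index[~bad][0]!r}")
        need_symbol = ann["probe_class"].isin([ENDOGENOUS, HOUSEKEEPING])
        symbols = ann["gene_symbol"].fillna("").astype(str).str.strip()
        empty = need_symbol & symbols.isin(["", "nan"])
        if empty.any():
            raise IntegrityError(f"probe {ann.index[empty][0]!r} has no gene symbol")

    # -- convenient views -------------------------------------------------
    def probes_of_class(self, probe_class: str) -> list[str]:
        ann = self.annotation
        return list(ann.index[ann["probe_class"] == probe_class])

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def counts_of_class(self, probe_class: str) -> pd.DataFrame:
        return self.counts[self.probes_of_class(probe_class)]

    def gene_symbols(self, probe_classes=(ENDOGENOUS, HOUSEKEEPING)) -> list[str]:
        ann = self.annotation
        mask = ann["probe_class"].isin(probe_classes)
        return list(ann.loc[mask, "gene_symbol"])

    def require_controls(self) -> None:
        """Enforce the normalization precondition on control probe presence."""
        for cls in (POSITIVE, NEGATIVE, HOUSEKEEPING):
            if not self.probes_of_class(cls):
                raise IntegrityError(f"matrix has no {cls} probes")


@dataclass
class MarkerPanel:
    """Cell type -> marker genes mapping with a pan-leukocyte reference gene."""

    cell_types: dict[str, list[str]]
    reference_gene: str = "PTPRC"
    cytotoxic_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cell, genes in self.cell_types.items():
            for g in genes:
                if g in seen:
                    raise IntegrityError(
                        f"marker {g} assigned to both {seen[g]!r} and {cell!r}"
                    )
                seen[g] = cell
        if self.reference_gene in seen:
            raise IntegrityError(
                f"reference gene {self.reference_gene} is itself a panel marker"
            )

    @property
    def marker_genes(self) -> list[str]:
        return [g for genes in self.cell_types.values() for g in genes]


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)


def read_count_table(path) -> RawCountMatrix:
    """Read a raw probe-count table in either orientation.

    Probes-as-rows layout: columns ``probe_id, gene_symbol, probe_class``
    then one column per sample.  Transposed layout: one column per probe,
    with the first rows labelled ``gene_symbol`` and ``probe_class`` in the
    leading column and subsequent rows holding one sample each.
    """
    df = _read_table(path)
    cols_lower = [c.strip().lower() for c in df.columns]
    if "probe_class" in cols_lower:
        df.columns = [c.strip() for c in df.columns]
        rename = {c: c.lower() for c in df.columns if c.lower() in
                  ("probe_id", "gene_symbol", "probe_class")}
        df = df.rename(columns=rename)
        sample_cols = [c for c in df.columns
                       if c not in ("probe_id", "gene_symbol", "probe_class")]
        if not sample_cols:
            raise FormatError(f"{path}: no sample columns found")
        ann = pd.DataFrame(
            {
                "gene_symbol": df["gene_symbol"].fillna("").str.strip().to_numpy(),
                "probe_class": [_canonical_class(c) for c in df["probe_class"]],
            },
            index=pd.Index(df["probe_id"].str.strip(), name="probe_id"),
        )
        counts = _coerce_counts(df[sample_cols].T, path)
        counts.columns = ann.index
        counts.index.name = "sample_id"
        return RawCountMatrix(counts=counts, annotation=ann)

    # transposed: annotation rows under the first column
    label_col = df.columns[0]
    labels = df[label_col].astype(str).str.strip().str.lower()
    if "probe_class" not in set(labels):
        raise FormatError(
            f"{path}: missing probe_class column (neither orientation matches)"
        )
    probe_ids = [c.strip() for c in df.columns[1:]]
    meta = {lab: df.loc[labels == lab].iloc[0, 1:] for lab in ("gene_symbol", "probe_class")}
    ann = pd.DataFrame(
        {
            "gene_symbol": meta["gene_symbol"].fillna("").astype(str).str.strip().to_numpy(),
            "probe_class": [_canonical_class(c) for c in meta["probe_class"]],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    sample_rows = df.loc[~labels.isin(("gene_symbol", "probe_class"))]
    counts = _coerce_counts(sample_rows.set_index(label_col)[df.columns[1:]], path)
    counts.columns = ann.index
    counts.index.name = "sample_id"
    return RawCountMatrix(counts=counts, annotation=ann)


def _coerce_counts(raw: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in raw.columns:
        try:
            numeric = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric count in column {col!r}: {exc}") from exc
        if (numeric < 0).any():
            row = numeric.index[numeric < 0][0]
            raise ValueError(f"{path}: negative count at row {row!r}, column {col!r}")
        out[col] = numeric.round().astype(np.int64)
    res = pd.DataFrame(out, index=raw.index)
    res.index = res.index.astype(str)
    return res


def write_count_table(matrix: RawCountMatrix, path) -> None:
    """Write in the probes-as-rows layout (round-trips with the reader)."""
    ann = matrix.annotation
    out = pd.DataFrame(
        {
            "probe_id": ann.index,
            "gene_symbol": ann["gene_symbol"].to_numpy(),
            "probe_class": ann["probe_class"].to_numpy(),
        }
    )
    for sample in matrix.counts.index:
        out[sample] = matrix.counts.loc[sample].to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical cohort table
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "dead", "event"}
_FALSY = {"0", "false", "no", "n", "alive", "censored"}


def _parse_event(value) -> bool:
    key = str(value).strip().lower()
    if key in _TRUTHY:
        return True
    if key in _FALSY:
        return False
    raise ValueError(f"cannot interpret event flag {value!r}")


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate the clinical table.

    Returns a DataFrame indexed by ``sample_id`` with validated required
    fields (``os_days``, ``event``, ``age_years``, ``pdl1_percent``) and any
    optional covariate columns retained as-is (missing values kept as NaN).
    Rows missing a required field are dropped with a warning; out-of-range
    values raise ``ValueError``.
    """
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    incomplete = df[list(REQUIRED_COHORT_COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{path}: dropped {int(incomplete.sum())} rows with missing required fields",
            stacklevel=2,
        )
        df = df.loc[~incomplete]

    out = pd.DataFrame(index=pd.Index(df["sample_id"].astype(str).str.strip(), name="sample_id"))
    if out.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample id {out.index[out.index.duplicated()][0]!r}")
    out["os_days"] = pd.to_numeric(df["os_days"]).to_numpy()
    out["event"] = [_parse_event(v) for v in df["event"]]
    out["age_years"] = pd.to_numeric(df["age_years"]).to_numpy()
    out["pdl1_percent"] = pd.to_numeric(df["pdl1_percent"]).to_numpy()
    if (out["os_days"] <= 0).any():
        bad = out.index[out["os_days"] <= 0][0]
        raise ValueError(f"{path}: os_days must be > 0 (sample {bad!r})")
    if ((out["pdl1_percent"] < 0) | (out["pdl1_percent"] > 100)).any():
        bad = out.index[(out["pdl1_percent"] < 0) | (out["pdl1_percent"] > 100)][0]
        raise ValueError(f"{path}: pdl1_percent outside [0, 100] (sample {bad!r})")
    if "sex" in df.columns:
        sex = df["sex"].astype(str).str.strip().str.lower()
        if not sex.isin(["male", "female"]).all():
            raise ValueError(f"{path}: sex must be male/female")
        out["sex"] = sex.to_numpy()
    for col in df.columns:
        if col not in REQUIRED_COHORT_COLUMNS and col != "sex":
            out[col] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    return out


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# IHC densities
# ---------------------------------------------------------------------------

def read_ihc_table(path) -> pd.DataFrame:
    """Read the IHC density table (sample x marker, positive cells/mm²).

    CD45 must be present for every sample carrying any other marker.
    """
    df = _read_table(path)
    df.columns = [c.strip() for c in df.columns]
    first = df.columns[0]
    out = df.set_index(first)
    out.index = out.index.astype(str)
    out.index.name = "sample_id"
    out = out.apply(pd.to_numeric)
    if (out.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative density")
    if "CD45" not in out.columns:
        raise FormatError(f"{path}: CD45 column required")
    others = [c for c in out.columns if c != "CD45"]
    bad = out["CD45"].isna() & out[others].notna().any(axis=1)
    if bad.any():
        raise IntegrityError(f"{path}: sample {out.index[bad][0]!r} has markers but no CD45")
    return out


def write_ihc_table(ihc: pd.DataFrame, path) -> None:
    ihc.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# Panels and gene lists
# ---------------------------------------------------------------------------

def _load_packaged_yaml(name: str) -> dict:
    with resources.files("mpeimmune.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def read_marker_panel(path=None) -> MarkerPanel:
    """Load a marker panel from YAML (or the packaged 13-cell-type default).

    YAML layout: ``cell_types: {name: [genes]}``, ``reference_gene``,
    optional ``cytotoxic_genes``.  A two-column TSV (cell_type, gene) is also
    accepted.
    """
    if path is None:
        raw = _load_packaged_yaml("marker_panel.yaml")
    else:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(path.read_text())
        else:
            df = _read_table(path)
            df.columns = [c.strip().lower() for c in df.columns]
            raw = {"cell_types": {}}
            for cell, sub in df.groupby(df.columns[0], sort=False):
                raw["cell_types"][cell] = list(sub[df.columns[1]])
    return MarkerPanel(
        cell_types={k: list(v) for k, v in raw["cell_types"].items()},
        reference_gene=raw.get("reference_gene", "PTPRC"),
        cytotoxic_genes=list(raw.get("cytotoxic_genes", [])),
    )


def read_clustering_panel(path=None) -> dict:
    """Load the 74-gene clustering panel with its A/B block annotation."""
    raw = _load_packaged_yaml("clustering_panel.yaml") if path is None \
        else yaml.safe_load(Path(path).read_text())
    panel = {
        "cluster_A": list(raw["cluster_A"]),
        "cluster_B": list(raw["cluster_B"]),
        "seed_cell_types": list(raw.get("seed_cell_types", [])),
    }
    overlap = set(panel["cluster_A"]) & set(panel["cluster_B"])
    if overlap:
        raise IntegrityError(f"genes in both blocks: {sorted(overlap)}")
    return panel


def read_modulator_list(path=None) -> dict:
    """Load the immunomodulator gene list with functional annotation."""
    raw = _load_packaged_yaml("immunomodulators.yaml") if path is None \
        else yaml.safe_load(Path(path).read_text())
    genes = dict(raw["genes"]) if isinstance(raw["genes"], dict) \
        else {g: "na" for g in raw["genes"]}
    return {
        "genes": genes,
        "cold_elevated": list(raw.get("cold_elevated", [])),
        "pathway_genes": list(raw.get("pathway_genes", [])),
    }
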