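"""Three-step nCounter count normalization followed by log2 transform.

The scheme follows the vendor-described procedure: (1) positive-control
scaling removes platform/lane variation, (2) the negative-control background
is subtracted with flooring at zero, (3) housekeeping scaling removes
sample-input variation, and finally counts are transformed as
``log2(x + pseudocount)``.  Scaling factors use the geometric-mean ratio
construction: ``factor_s = mean_over_samples(geomean_s) / geomean_s`` so that
after scaling every sample has the same control geometric mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .io import ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE, RawCountMatrix

BACKGROUND_MEAN = "mean"
BACKGROUND_MEAN_2SD = "mean_plus_2sd"


@dataclass
class NormalizationFactors:
    """Per-sample factors applied during normalization."""

    positive_factor: pd.Series
    background_level: pd.Series
    housekeeping_factor: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "positive_factor": self.positive_factor,
                "background_level": self.background_level,
                "housekeeping_factor": self.housekeeping_factor,
            }
        )


@dataclass
class ExpressionMatrix:
    """Samples x genes of log2 normalized expression with provenance."""

    values: pd.DataFrame
    factors: NormalizationFactors | None = None
    pseudocount: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def _geometric_means(block: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of a counts block (rows = samples)."""
    vals = block.to_numpy(dtype=float)
    if (vals <= 0).any():
        s, p = np.argwhere(vals <= 0)[0]
        raise NormalizationError(
            f"non-positive control count for sample {block.index[s]!r} "
            f"(probe {block.columns[p]!r})"
        )
    return pd.Series(np.exp(np.log(vals).mean(axis=1)), index=block.index)


def _ratio_factors(geomeans: pd.Series) -> pd.Series:
    """Factors equalizing geometric means to their arithmetic mean."""
    return geomeans.mean() / geomeans


def positive_control_factors(raw: RawCountMatrix) -> pd.Series:
    """Per-sample scaling factors from the positive-control probes."""
    raw.require_controls()
    return _ratio_factors(_geometric_means(raw.counts_of_class(POSITIVE)))


def subtract_background(raw: RawCountMatrix, method: str = BACKGROUND_MEAN,
                        scaled: pd.DataFrame | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Remove the negative-control background from endogenous+housekeeping counts.

    ``scaled`` allows background removal on counts already rescaled by the
    positive-control factors; the background level is then computed from the
    equally rescaled negative controls.  Returns the floored counts (samples
    x probes, endogenous and housekeeping only) and the per-sample background
    level.
    """
    neg_probes = raw.probes_of_class(NEGATIVE)
    if not neg_probes:
        raise NormalizationError("matrix has no negative-control probes")
    counts = raw.counts.astype(float) if scaled is None else scaled
    negatives = counts[neg_probes]
    if method == BACKGROUND_MEAN:
        level = negatives.mean(axis=1)
    elif method == BACKGROUND_MEAN_2SD:
        level = negatives.mean(axis=1) + 2.0 * negatives.std(axis=1, ddof=1)
    else:
        raise NormalizationError(f"unknown background method {method!r}")
    target = raw.probes_of_class(ENDOGENOUS) + raw.probes_of_class(HOUSEKEEPING)
    floored = (counts[target].sub(level, axis=0)).clip(lower=0.0)
    return floored, level


def housekeeping_factors(counts: pd.DataFrame, raw: RawCountMatrix,
                         housekeeping_genes=None) -> pd.Series:
    """Per-sample factors from housekeeping genes on background-removed counts.

    ``housekeeping_genes`` selects a gene-symbol subset (default: all
    housekeeping probes).  Genes at zero in any sample after background
    removal are excluded with a warning; fewer than 3 usable genes is an
    error.
    """
    ann = raw.annotation
    hk_probes = raw.probes_of_class(HOUSEKEEPING)
    if housekeeping_genes is not None:
        wanted = set(housekeeping_genes)
        hk_probes = [p for p in hk_probes if ann.loc[p, "gene_symbol"] in wanted]
    hk_probes = [p for p in hk_probes if p in counts.columns]
    block = counts[hk_probes]
    usable = [p for p in hk_probes if (block[p] > 0).all()]
    dropped = sorted(set(hk_probes) - set(usable))
    if dropped:
        warnings.warn(
            f"housekeeping probes at zero after background removal, excluded: {dropped}",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise NormalizationError(
            f"only {len(usable)} usable housekeeping genes (need >= 3)"
        )
    return _ratio_factors(_geometric_means(block[usable]))


def normalize(raw: RawCountMatrix, background_method: str = BACKGROUND_MEAN,
              pseudocount: float = 1.0, housekeeping_genes=None) -> ExpressionMatrix:
    """Full normalization: positive -> background -> housekeeping -> log2.

    Returns an :class:`ExpressionMatrix` over gene symbols (endogenous and
    housekeeping probes collapse to their symbols; the panel carries one
    probe per gene) with the applied factors recorded in provenance.
    """
    raw.require_controls()
    pos = positive_control_factors(raw)
    scaled = raw.counts.astype(float).mul(pos, axis=0)
    floored, level = subtract_background(raw, method=background_method, scaled=scaled)
    hk = housekeeping_factors(floored, raw, housekeeping_genes=housekeeping_genes)
    final = floored.mul(hk, axis=0)
    values = np.log2(final + pseudocount)
    symbols = raw.annotation.loc[values.columns, "gene_symbol"]
    values.columns = symbols.to_numpy()
    if pd.Index(values.columns).duplicated().any():
        # one probe per gene is the panel design; collapse defensively by mean
        values = values.T.groupby(level=0).mean().T
    factors = NormalizationFactors(
        positive_factor=pos, background_level=level, housekeeping_factor=hk
    )
    return ExpressionMatrix(
        values=values,
        factors=factors,
        pseudocount=pseudocount,
        meta={"background_method": background_method,
              "housekeeping_genes": None if housekeeping_genes is None
              else list(housekeeping_genes)},
    )


def default_qc_threshold(raw: RawCountMatrix, pseudocount: float = 1.0) -> float:
    """Background-derived marker QC floor in log2 units.

    log2(mean negative-control count + pseudocount), averaged over samples —
    the expression level a probe must exceed to be distinguishable from
    background.
    """
    neg = raw.counts_of_class(NEGATIVE).to_numpy(dtype=float)
    return float(np.log2(neg.mean() + pseudocount))
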