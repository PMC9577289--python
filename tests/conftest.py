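import numpy as np
import pandas as pd
import pytest

from mpeimmune import (GeneratorConfig, RawCountMatrix, generate, normalize,
                       read_marker_panel)


def make_raw(counts: dict, classes: dict, symbols: dict | None = None,
             samples=None) -> RawCountMatrix:
    """Build a RawCountMatrix from per-probe count lists."""
    probes = list(counts)
    samples = samples or [f"S{i + 1}" for i in range(len(next(iter(counts.values()))))]
    cnt = pd.DataFrame({p: counts[p] for p in probes},
                       index=pd.Index(samples, name="sample_id"))
    ann = pd.DataFrame(
        {
            "gene_symbol": [(symbols or {}).get(
                p, "" if classes[p].lower().startswith(("pos", "neg")) else p)
                for p in probes],
            "probe_class": [classes[p] for p in probes],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return RawCountMatrix(counts=cnt, annotation=ann)


@pytest.fixture
def tiny_raw() -> RawCountMatrix:
    """Smallest valid input: 2 samples x 4 probes, one probe of each class."""
    return make_raw(
        counts={"GENE1": [10, 20], "POS_1": [100, 200], "NEG_1": [2, 4],
                "HK1": [50, 100]},
        classes={"GENE1": "endogenous", "POS_1": "positive",
                 "NEG_1": "negative", "HK1": "housekeeping"},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 1)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_expr(default_cohort):
    return normalize(default_cohort.raw)


@pytest.fixture(scope="session")
def marker_panel():
    return read_marker_panel()


def correlated_vector(rng: np.random.Generator, ref: np.ndarray,
                      r: float) -> np.ndarray:
    """A vector with exact Pearson correlation ``r`` to ``ref``."""
    z = (ref - ref.mean()) / ref.std()
    e = rng.normal(size=len(ref))
    e = e - e.mean()
    e = e - z * (e @ z) / (z @ z)          # orthogonalize
    e = e / np.sqrt((e ** 2).mean())
    return r * z + np.sqrt(1 - r ** 2) * e
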