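import numpy as np
import pandas as pd
import pytest

from mpeimmune import (NormalizationError, default_qc_threshold,
                       housekeeping_factors, normalize,
                       positive_control_factors, subtract_background)
from conftest import make_raw


def two_sample_fixture():
    """Hand example: pos geomeans 200 / 400, reference 300."""
    return make_raw(
        counts={
            "G1": [10, 40], "G2": [30, 10],
            "POS_1": [100, 200], "POS_2": [400, 800],
            "NEG_1": [2, 2], "NEG_2": [4, 4], "NEG_3": [6, 6],
            "HK1": [64, 128], "HK2": [64, 128], "HK3": [64, 128],
        },
        classes={"G1": "endogenous", "G2": "endogenous",
                 "POS_1": "positive", "POS_2": "positive",
                 "NEG_1": "negative", "NEG_2": "negative", "NEG_3": "negative",
                 "HK1": "housekeeping", "HK2": "housekeeping", "HK3": "housekeeping"},
        samples=["A", "B"],
    )


class TestPositiveFactors:
    def test_hand_geometric_means(self):
        f = positive_control_factors(two_sample_fixture())
        np.testing.assert_allclose(f["A"], 1.5)
        np.testing.assert_allclose(f["B"], 0.75)

    def test_identical_samples_give_unit_factors(self):
        raw = make_raw(
            counts={"G": [5, 5], "P": [100, 100], "N": [2, 2], "H": [50, 50]},
            classes={"G": "endogenous", "P": "positive", "N": "negative",
                     "H": "housekeeping"},
        )
        np.testing.assert_allclose(positive_control_factors(raw), 1.0)

    def test_homogeneity_scaling_one_sample(self):
        raw = two_sample_fixture()
        base = positive_control_factors(raw)
        scaled = raw.counts.copy()
        scaled.loc["A", ["POS_1", "POS_2"]] *= 4
        raw2 = make_raw(
            counts={c: scaled[c].tolist() for c in scaled.columns},
            classes=raw.annotation.probe_class.to_dict(),
            samples=["A", "B"],
        )
        f2 = positive_control_factors(raw2)
        # scaling sample A's positives by c divides its factor by c (up to the
        # common reference, which rescales both factors equally)
        np.testing.assert_allclose(f2["A"] / f2["B"], (base["A"] / 4) / base["B"])

    def test_zero_positive_count_is_error(self):
        raw = make_raw(
            counts={"G": [5, 5], "P": [0, 100], "N": [2, 2], "H": [50, 50]},
            classes={"G": "endogenous", "P": "positive", "N": "negative",
                     "H": "housekeeping"},
        )
        with pytest.raises(NormalizationError, match="S1"):
            positive_control_factors(raw)


class TestBackground:
    def test_mean_of_negatives_subtracted(self):
        raw = make_raw(
            counts={"G": [10], "N1": [2], "N2": [4], "N3": [6],
                    "P": [100], "H": [50]},
            classes={"G": "endogenous", "N1": "negative", "N2": "negative",
                     "N3": "negative", "P": "positive", "H": "housekeeping"},
        )
        floored, level = subtract_background(raw)
        assert level["S1"] == 4.0
        assert floored.loc["S1", "G"] == 6.0

    def test_floor_at_zero(self):
        raw = make_raw(
            counts={"G": [3], "N1": [4], "P": [100], "H": [50]},
            classes={"G": "endogenous", "N1": "negative", "P": "positive",
                     "H": "housekeeping"},
        )
        floored, _ = subtract_background(raw)
        assert floored.loc["S1", "G"] == 0.0

    def test_zero_background_is_identity(self):
        raw = make_raw(
            counts={"G": [10], "N1": [0], "P": [100], "H": [50]},
            classes={"G": "endogenous", "N1": "negative", "P": "positive",
                     "H": "housekeeping"},
        )
        floored, level = subtract_background(raw)
        assert level["S1"] == 0.0
        assert floored.loc["S1", "G"] == 10.0

    def test_mean_plus_2sd_method(self):
        raw = two_sample_fixture()
        _, level = subtract_background(raw, method="mean_plus_2sd")
        np.testing.assert_allclose(level["A"], 4.0 + 2 * 2.0)


class TestHousekeeping:
    def test_twofold_samples_give_2_to_1_factors(self):
        raw = two_sample_fixture()
        floored, _ = subtract_background(raw)
        f = housekeeping_factors(floored, raw)
        np.testing.assert_allclose(f["A"] / f["B"], (128 - 4) / (64 - 4))

    def test_hand_geometric_mean_arithmetic(self):
        raw = make_raw(
            counts={"G": [5, 5], "P": [100, 100], "N": [0, 0],
                    "H1": [100, 200], "H2": [400, 800], "H3": [200, 400]},
            classes={"G": "endogenous", "P": "positive", "N": "negative",
                     "H1": "housekeeping", "H2": "housekeeping",
                     "H3": "housekeeping"},
            samples=["A", "B"],
        )
        floored, _ = subtract_background(raw)
        f = housekeeping_factors(floored, raw)
        np.testing.assert_allclose(f["A"], 1.5)
        np.testing.assert_allclose(f["B"], 0.75)

    def test_too_few_usable_housekeepers_is_error(self):
        raw = make_raw(
            counts={"G": [5, 5], "P": [100, 100], "N": [0, 0],
                    "H1": [0, 10], "H2": [0, 10], "H3": [5, 10]},
            classes={"G": "endogenous", "P": "positive", "N": "negative",
                     "H1": "housekeeping", "H2": "housekeeping",
                     "H3": "housekeeping"},
        )
        floored, _ = subtract_background(raw)
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(NormalizationError, match="usable housekeeping"):
                housekeeping_factors(floored, raw)


class TestNormalize:
    def test_constant_matrix_stays_constant(self):
        raw = make_raw(
            counts={"G1": [40, 40], "G2": [40, 40], "P": [100, 100],
                    "N": [0, 0], "H1": [40, 40], "H2": [40, 40], "H3": [40, 40]},
            classes={"G1": "endogenous", "G2": "endogenous", "P": "positive",
                     "N": "negative", "H1": "housekeeping",
                     "H2": "housekeeping", "H3": "housekeeping"},
        )
        expr = normalize(raw)
        np.testing.assert_allclose(expr.values.to_numpy(), np.log2(41.0))

    def test_pipeline_equals_manual_composition(self):
        raw = two_sample_fixture()
        expr = normalize(raw)
        pos = positive_control_factors(raw)
        scaled = raw.counts.astype(float).mul(pos, axis=0)
        floored, _ = subtract_background(raw, scaled=scaled)
        hk = housekeeping_factors(floored, raw)
        manual = np.log2(floored.mul(hk, axis=0) + 1.0)
        manual.columns = raw.annotation.loc[manual.columns, "gene_symbol"].to_numpy()
        pd.testing.assert_frame_equal(expr.values, manual)

    def test_housekeeping_geomeans_equalized_on_generator(self, default_cohort,
                                                          default_expr):
        hk_genes = default_cohort.raw.gene_symbols(["housekeeping"])
        final_counts = 2.0 ** default_expr.values[hk_genes] - 1.0
        geomeans = np.exp(np.log(final_counts).mean(axis=1))
        assert geomeans.max() - geomeans.min() < 1e-9 * geomeans.mean()

    def test_positive_geomeans_equalized_after_scaling(self, default_cohort):
        raw = default_cohort.raw
        pos = positive_control_factors(raw)
        scaled = raw.counts_of_class("positive").mul(pos, axis=0)
        geomeans = np.exp(np.log(scaled).mean(axis=1))
        np.testing.assert_allclose(geomeans, geomeans.iloc[0])

    def test_monotone_in_raw_count(self):
        raw = two_sample_fixture()
        expr1 = normalize(raw)
        bumped = raw.counts.copy()
        bumped.loc["A", "G1"] += 10
        raw2 = make_raw(counts={c: bumped[c].tolist() for c in bumped.columns},
                        classes=raw.annotation.probe_class.to_dict(),
                        samples=["A", "B"])
        expr2 = normalize(raw2)
        assert expr2.values.loc["A", "G1"] > expr1.values.loc["A", "G1"]

    def test_qc_threshold_from_negatives(self, tiny_raw):
        # tiny fixture negatives: 2 and 4 -> mean 3 -> log2(4)
        assert default_qc_threshold(tiny_raw) == pytest.approx(2.0)
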