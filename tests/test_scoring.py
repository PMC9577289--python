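import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpeimmune import (ExpressionMatrix, MarkerPanel, compute_cell_scores,
                       compute_tils_score, cytotoxic_composite,
                       default_qc_threshold, marker_qc_filter, normalize,
                       read_marker_panel, relative_scores, score_pipeline)
from conftest import correlated_vector


def expr_from(values: dict, n=None) -> ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = [f"S{i + 1}" for i in range(len(df))]
    return ExpressionMatrix(values=df)


class TestQCFilter:
    def test_threshold_minus_inf_is_identity(self):
        panel = MarkerPanel(cell_types={"T": ["A", "B"]})
        expr = expr_from({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        filtered, report = marker_qc_filter(expr, panel, -np.inf)
        assert filtered.cell_types == panel.cell_types
        assert report["dropped"] == {}

    def test_marker_at_zero_dropped_at_threshold_one(self):
        panel = MarkerPanel(cell_types={"T": ["A", "B"]})
        expr = expr_from({"A": [0.0, 0.0], "B": [3.0, 4.0]})
        filtered, report = marker_qc_filter(expr, panel, 1.0)
        assert filtered.cell_types == {"T": ["B"]}
        assert report["dropped"] == {"T": ["A"]}

    def test_exactly_the_low_markers_dropped(self):
        panel = MarkerPanel(cell_types={"T": ["A", "B", "C", "D", "E"]})
        expr = expr_from({"A": [5.0], "B": [0.5], "C": [6.0], "D": [0.2],
                          "E": [7.0]})
        filtered, report = marker_qc_filter(expr, panel, 1.0)
        assert filtered.cell_types["T"] == ["A", "C", "E"]
        assert sorted(report["dropped"]["T"]) == ["B", "D"]

    def test_cell_type_losing_all_markers_flagged_unscorable(self):
        panel = MarkerPanel(cell_types={"T": ["A"], "B cells": ["B"]})
        expr = expr_from({"A": [0.0], "B": [5.0]})
        filtered, report = marker_qc_filter(expr, panel, 1.0)
        assert report["unscorable"] == ["T"]
        assert "T" not in filtered.cell_types


class TestCellScores:
    def test_single_marker_score_equals_gene(self):
        panel = MarkerPanel(cell_types={"T": ["A"]})
        expr = expr_from({"A": [4.0, 5.0]})
        table = compute_cell_scores(expr, panel)
        np.testing.assert_allclose(table.scores["T"], [4.0, 5.0])

    def test_mean_of_three_markers(self):
        panel = MarkerPanel(cell_types={"T": ["A", "B", "C"]})
        expr = expr_from({"A": [4.0], "B": [6.0], "C": [8.0]})
        assert compute_cell_scores(expr, panel).scores.loc["S1", "T"] == 6.0

    def test_marker_order_irrelevant(self):
        expr = expr_from({"A": [4.0, 1.0], "B": [6.0, 2.0], "C": [8.0, 3.0]})
        s1 = compute_cell_scores(expr, MarkerPanel(cell_types={"T": ["A", "B", "C"]}))
        s2 = compute_cell_scores(expr, MarkerPanel(cell_types={"T": ["C", "A", "B"]}))
        pd.testing.assert_frame_equal(s1.scores, s2.scores)

    def test_matches_bruteforce_loops(self, default_expr, marker_panel):
        table = compute_cell_scores(default_expr, marker_panel)
        values = default_expr.values
        for cell, genes in marker_panel.cell_types.items():
            for sample in values.index[:10]:
                acc = 0.0
                for g in genes:
                    acc += values.loc[sample, g]
                assert abs(acc / len(genes) - table.scores.loc[sample, cell]) < 1e-12


class TestTILs:
    def _table_with_correlations(self, rs: dict, n=40, seed=0):
        rng = np.random.default_rng(seed)
        ref = np.linspace(0.0, 5.0, n) + rng.normal(0, 0.1, n)
        cols = {"PTPRC": ref}
        for cell, r in rs.items():
            cols[f"{cell}_marker"] = correlated_vector(rng, ref, r) + 6.0
        expr = expr_from(cols)
        panel = MarkerPanel(cell_types={c: [f"{c}_marker"] for c in rs})
        table = compute_cell_scores(expr, panel)
        return table, expr

    def test_gate_keeps_cells_above_r_min(self):
        table, expr = self._table_with_correlations({"T": 0.9, "B": 0.7, "Mac": 0.5})
        out = compute_tils_score(table, expr, r_min=0.6)
        assert set(out.tils_members) == {"T", "B"}
        np.testing.assert_allclose(
            out.tils, table.scores[["T", "B"]].mean(axis=1))

    def test_single_perfectly_correlated_cell(self):
        table, expr = self._table_with_correlations({"T": 1.0})
        out = compute_tils_score(table, expr, r_min=0.6)
        np.testing.assert_allclose(out.tils, table.scores["T"])

    def test_empty_gate_warns_and_undefined(self):
        table, expr = self._table_with_correlations({"T": -0.8, "B": -0.5})
        with pytest.warns(UserWarning, match="TILs score undefined"):
            out = compute_tils_score(table, expr, r_min=0.6)
        assert out.tils is None

    def test_gate_monotone_in_r_min(self):
        table, expr = self._table_with_correlations(
            {"T": 0.9, "B": 0.7, "Mac": 0.5, "NK": 0.65})
        members = []
        for r_min in (0.4, 0.6, 0.8):
            out = compute_tils_score(table, expr, r_min=r_min)
            members.append(set(out.tils_members))
        assert members[2] <= members[1] <= members[0]


class TestRelativeAndCytotoxic:
    def test_relative_zero_when_score_equals_tils(self):
        table, expr = TestTILs()._table_with_correlations({"T": 1.0})
        out = compute_tils_score(table, expr, r_min=0.6)
        np.testing.assert_allclose(relative_scores(out)["T"], 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.floats(-5, 5))
    def test_shift_invariance_of_relatives(self, shift):
        table, expr = TestTILs()._table_with_correlations({"T": 0.9, "B": 0.8})
        out = compute_tils_score(table, expr, r_min=0.6)
        shifted = ExpressionMatrix(values=expr.values + shift)
        panel = MarkerPanel(cell_types={c: [f"{c}_marker"] for c in ("T", "B")})
        out2 = compute_tils_score(
            compute_cell_scores(shifted, panel), shifted, r_min=0.6)
        pd.testing.assert_frame_equal(out.relative, out2.relative,
                                      check_exact=False, atol=1e-9)

    def test_single_gene_composite(self):
        expr = expr_from({"GZMA": [4.0, 7.0]})
        np.testing.assert_allclose(cytotoxic_composite(expr, ["GZMA"]), [4.0, 7.0])

    def test_empty_surviving_list_is_error(self):
        expr = expr_from({"GZMA": [4.0]})
        with pytest.raises(ValueError):
            cytotoxic_composite(expr, [])
        with pytest.warns(UserWarning, match="missing"):
            with pytest.raises(ValueError, match="no cytotoxic genes"):
                cytotoxic_composite(expr, ["NOPE"])

    def test_composite_higher_in_adaptive_archetypes(self, default_cohort,
                                                     default_expr, marker_panel):
        comp = cytotoxic_composite(default_expr, marker_panel.cytotoxic_genes)
        hot = default_cohort.truth.temperature == "hot"
        assert comp[hot].mean() > comp[~hot].mean() + 1.0


class TestEndToEndDirections:
    def test_hot_cold_relative_directions_match_study(self, default_cohort,
                                                      default_expr, marker_panel):
        """Hot effusions: higher CD8/TILs; cold: higher macrophage and
        neutrophil relatives."""
        qc = default_qc_threshold(default_cohort.raw)
        out = score_pipeline(default_expr, marker_panel, qc_threshold=qc)
        assert out.tils is not None
        hot = default_cohort.truth.temperature == "hot"
        rel = out.relative
        assert rel.loc[hot, "CD8 T cells"].mean() > rel.loc[~hot, "CD8 T cells"].mean()
        assert rel.loc[~hot, "Macrophages"].mean() > rel.loc[hot, "Macrophages"].mean()
        assert rel.loc[~hot, "Neutrophils"].mean() > rel.loc[hot, "Neutrophils"].mean()
        # TILs gate admits the lymphocyte scores
        assert {"T cells", "B cells", "CD8 T cells"} <= set(out.tils_members)
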