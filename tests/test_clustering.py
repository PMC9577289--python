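import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

from mpeimmune import (ExpressionMatrix, GeneratorConfig, assign_patients,
                       cut_k, generate, normalize, partition_genes,
                       read_clustering_panel, read_marker_panel, ward_linkage)
from _oracles import brute_force_ward


class TestWardLinkage:
    def test_two_vectors_merge_at_their_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        for variant in ("ward_d", "ward_d2"):
            z = ward_linkage(pts, variant=variant)
            assert z.shape == (1, 4)
            assert z[0, 2] == pytest.approx(5.0)

    @pytest.mark.parametrize("variant", ["ward_d", "ward_d2"])
    def test_two_tight_pairs_recovered(self, variant):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = cut_k(ward_linkage(pts, variant=variant), 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    @pytest.mark.parametrize("variant,squared", [("ward_d", False),
                                                 ("ward_d2", True)])
    def test_matches_bruteforce_lance_williams(self, variant, squared):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        z = ward_linkage(pts, variant=variant)
        expected = brute_force_ward(pts, squared=squared)
        np.testing.assert_allclose(sorted(z[:, 2]), expected, atol=1e-9)

    def test_ward_d2_matches_scipy(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 4))
        z = ward_linkage(pts, variant="ward_d2")
        ref = scipy_linkage(pts, method="ward")
        np.testing.assert_allclose(sorted(z[:, 2]), sorted(ref[:, 2]), atol=1e-9)
        assert (cut_k(z, 3) == cut_k(z, 3)).all()
        # same flat partition at k=3
        a, b = cut_k(z, 3), ref
        from scipy.cluster.hierarchy import fcluster
        b3 = fcluster(ref, 3, criterion="maxclust")
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a, b3) == 1.0

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 5))
        for variant in ("ward_d", "ward_d2"):
            h = ward_linkage(pts, variant=variant)[:, 2]
            assert (np.diff(h) >= -1e-12).all()

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ward_linkage(np.array([[0.0], [np.nan]]))

    def test_determinism(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(ward_linkage(pts), ward_linkage(pts))


def _block_expr(n_samples=30, seed=0):
    """Two uncorrelated gene blocks driven by independent latent factors."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n_samples)
    f2 = rng.normal(size=n_samples)
    cols = {}
    for i in range(5):
        cols[f"A{i}"] = 3 * f1 + rng.normal(0, 0.3, n_samples)
    for i in range(5):
        cols[f"B{i}"] = 3 * f2 + rng.normal(0, 0.3, n_samples)
    df = pd.DataFrame(cols, index=[f"S{i}" for i in range(n_samples)])
    return ExpressionMatrix(values=df)


class TestGenePartition:
    def test_two_blocks_exactly_recovered(self):
        expr = _block_expr()
        part = partition_genes(expr, list(expr.values.columns), seed_genes=["A0"])
        assert sorted(part.cluster_A_genes) == [f"A{i}" for i in range(5)]
        assert sorted(part.cluster_B_genes) == [f"B{i}" for i in range(5)]

    def test_label_A_follows_seed_block(self):
        expr = _block_expr()
        part = partition_genes(expr, list(expr.values.columns), seed_genes=["B2"])
        assert sorted(part.cluster_A_genes) == [f"B{i}" for i in range(5)]

    def test_generator_panel_blocks_recovered(self, default_cohort, default_expr):
        panel = read_clustering_panel()
        mp = read_marker_panel()
        seeds = [g for cell in panel["seed_cell_types"]
                 for g in mp.cell_types[cell]]
        part = partition_genes(default_expr,
                               panel["cluster_A"] + panel["cluster_B"], seeds)
        true_a = set(panel["cluster_A"])
        agree = (sum(g in true_a for g in part.cluster_A_genes)
                 + sum(g not in true_a for g in part.cluster_B_genes)) / 74
        assert agree >= 0.95

    def test_fewer_than_two_genes_is_error(self):
        expr = _block_expr()
        with pytest.raises(ValueError):
            partition_genes(expr, ["A0"], seed_genes=["A0"])


def _archetype_expr(n_per=6, gap=3.0, seed=0):
    """Four clean archetype blocks over 6 A-genes and 6 B-genes."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for ci, (a, b) in enumerate([(1, 1), (1, 0), (0, 0), (0, 1)]):
        for _ in range(n_per):
            rows.append(np.concatenate([
                a * gap + rng.normal(0, 0.1, 6),
                b * gap + rng.normal(0, 0.1, 6),
            ]))
            labels.append(f"C{ci + 1}")
    df = pd.DataFrame(rows, columns=[f"A{i}" for i in range(6)]
                      + [f"B{i}" for i in range(6)],
                      index=[f"S{i}" for i in range(len(rows))])
    return ExpressionMatrix(values=df), labels


class TestAssignPatients:
    def _partition(self, expr):
        return partition_genes(expr, list(expr.values.columns), seed_genes=["A0"])

    def test_four_archetypes_exact_recovery(self):
        expr, labels = _archetype_expr()
        out = assign_patients(expr, self._partition(expr))
        assert list(out["cluster"]) == labels

    def test_invariant_c_label_composition(self):
        expr, _ = _archetype_expr(seed=2)
        out = assign_patients(expr, self._partition(expr))
        comp = {("hot", "plus"): "C1", ("hot", "minus"): "C2",
                ("cold", "minus"): "C3", ("cold", "plus"): "C4"}
        for _, row in out.iterrows():
            assert comp[(row.temperature, row.innate)] == row.cluster

    def test_sample_relabelling_equivariance(self):
        expr, _ = _archetype_expr(seed=3)
        out1 = assign_patients(expr, self._partition(expr))
        renamed = ExpressionMatrix(
            values=expr.values.rename(index=lambda s: "X" + s))
        out2 = assign_patients(renamed, self._partition(renamed))
        assert list(out1["cluster"]) == list(out2["cluster"])

    def test_median_split_mode_agrees_on_separable_data(self):
        expr, labels = _archetype_expr(seed=4)
        out = assign_patients(expr, self._partition(expr), method="median")
        assert list(out["cluster"]) == labels

    def test_determinism_on_generator_cohort(self, default_expr):
        panel = read_clustering_panel()
        genes = panel["cluster_A"] + panel["cluster_B"]
        part = partition_genes(default_expr, genes, seed_genes=panel["cluster_A"][:5])
        a1 = assign_patients(default_expr, part)
        a2 = assign_patients(default_expr, part)
        pd.testing.assert_frame_equal(a1, a2)
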