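"""Diversity-metric tests against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from dilasm.containers import CommunityMatrix, DistanceMatrix
from dilasm.diversity import (
    bray_curtis,
    nmds,
    patristic_distances,
    rarefy,
    shannon,
    shannon_per_sample,
    weighted_unifrac,
)
from dilasm.synthetic import build_phylogeny
from tests.conftest import random_community


class TestRarefy:
    def test_identity_at_full_depth(self):
        m = CommunityMatrix(pd.DataFrame({"s": [6, 4]}, index=["a", "b"]))
        out = rarefy(m, 10, seed=1)
        assert out.table["s"].tolist() == [6, 4]

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(0)
        m = CommunityMatrix(
            pd.DataFrame(rng.integers(0, 50, (30, 5)) + 1, columns=list("abcde"))
        )
        out = rarefy(m, 100, seed=2)
        assert (out.table.sum(axis=0) == 100).all()

    def test_error_names_shallow_sample(self):
        m = CommunityMatrix(pd.DataFrame({"deep": [50, 50], "shallow": [2, 1]}))
        with pytest.raises(ValueError, match="shallow"):
            rarefy(m, 10, seed=0)

    def test_hypergeometric_mean(self):
        # column (6,4) rarefied to 5: first-taxon count is hypergeometric
        # with mean 5*6/10 = 3 and variance 5*.6*.4*(5/9)
        m = CommunityMatrix(pd.DataFrame({"s": [6, 4]}, index=["a", "b"]))
        draws = [rarefy(m, 5, seed=s).table.loc["a", "s"] for s in range(3000)]
        se = np.sqrt(5 * 0.6 * 0.4 * (5 / 9) / 3000)
        assert np.mean(draws) == pytest.approx(3.0, abs=3 * se)


class TestShannon:
    def test_single_taxon_is_zero(self):
        assert shannon(np.array([7.0])) == 0.0

    def test_uniform_is_log_richness(self):
        assert shannon(np.ones(17)) == pytest.approx(np.log(17))

    def test_hand_computed_value(self):
        assert shannon(np.array([1, 1, 2])) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon(np.zeros(3))

    def test_base_conversion(self):
        assert shannon(np.ones(8), base=2) == pytest.approx(3.0)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        m = CommunityMatrix(pd.DataFrame({"x": [3, 1], "y": [3, 1]}))
        assert bray_curtis(m)["x", "y"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        m = CommunityMatrix(pd.DataFrame({"x": [3, 0], "y": [0, 5]}))
        assert bray_curtis(m)["x", "y"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        m = CommunityMatrix(pd.DataFrame({"x": [1, 1, 0], "y": [0, 1, 1]}))
        assert bray_curtis(m)["x", "y"] == pytest.approx(0.5)

    def test_invariant_to_taxon_row_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.integers(0, 20, (12, 4)) + 1, columns=list("wxyz"))
        m = CommunityMatrix(df)
        shuffled = CommunityMatrix(df.sample(frac=1, random_state=1))
        np.testing.assert_allclose(bray_curtis(m).data, bray_curtis(shuffled).data)


def unifrac_bruteforce(tree, table: pd.DataFrame, normalized: bool) -> np.ndarray:
    """Independent oracle: explicit per-branch descendant-set enumeration."""
    rel = table / table.sum(axis=0)
    n = table.shape[1]
    d = np.zeros((n, n))
    depths = {}
    node_depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node_depth[node]
    for i in range(n):
        for j in range(i + 1, n):
            pa = rel.iloc[:, i]
            pb = rel.iloc[:, j]
            raw = 0.0
            for node in tree.preorder_node_iter():
                if node is tree.seed_node or node.edge.length is None:
                    continue
                desc = {leaf.taxon.label for leaf in node.leaf_iter()}
                ma = sum(pa.get(t, 0.0) for t in desc)
                mb = sum(pb.get(t, 0.0) for t in desc)
                raw += node.edge.length * abs(ma - mb)
            if normalized:
                denom = sum(
                    depths[t] * (pa.get(t, 0.0) + pb.get(t, 0.0)) for t in depths
                )
                raw = raw / denom if denom > 0 else 0.0
            d[i, j] = d[j, i] = raw
    return d


class TestWeightedUnifrac:
    def test_identical_columns_zero(self, toy_tree):
        m = CommunityMatrix(pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3]}, index=list("ABC")))
        assert weighted_unifrac(toy_tree, m)["x", "y"] == pytest.approx(0.0)

    def test_toy_tree_hand_computation(self, toy_tree, toy_community):
        raw = weighted_unifrac(toy_tree, toy_community, normalized=False)
        norm = weighted_unifrac(toy_tree, toy_community, normalized=True)
        assert raw["X", "Y"] == pytest.approx(4.0)
        assert norm["X", "Y"] == pytest.approx(1.0)

    def test_missing_taxon_errors(self, toy_tree):
        m = CommunityMatrix(pd.DataFrame({"x": [1, 1], "y": [1, 0]}, index=["A", "ZZ"]))
        with pytest.raises(ValueError, match="ZZ"):
            weighted_unifrac(toy_tree, m)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_against_bruteforce_oracle(self, normalized):
        rng = np.random.default_rng(11)
        for trial in range(12):
            tree = build_phylogeny(int(rng.integers(4, 33)), 1.0, seed=trial)
            tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
            m = random_community(rng, tips, n_samples=3)
            got = weighted_unifrac(tree, m, normalized=normalized)
            want = unifrac_bruteforce(tree, m.table, normalized)
            np.testing.assert_allclose(got.data, want, atol=1e-10)

    def test_normalized_bounded_in_unit_interval(self):
        rng = np.random.default_rng(21)
        for trial in range(25):
            tree = build_phylogeny(16, 1.0, seed=100 + trial)
            tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
            m = random_community(rng, tips, n_samples=4)
            d = weighted_unifrac(tree, m, normalized=True)
            assert d.data.min() >= -1e-12 and d.data.max() <= 1 + 1e-12

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity import beta_diversity
        from skbio.tree import TreeNode

        rng = np.random.default_rng(5)
        tree = build_phylogeny(20, 1.0, seed=9)
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        m = random_community(rng, tips, n_samples=4)
        from dilasm.trees import write_newick

        sk_tree = TreeNode.read([write_newick(tree)])
        counts = m.table.T.reindex(columns=tips, fill_value=0)
        ref = beta_diversity(
            "weighted_unifrac", counts.to_numpy().astype(int), ids=list(counts.index),
            taxa=tips, tree=sk_tree, normalized=False,
        )
        got = weighted_unifrac(tree, m, normalized=False)
        np.testing.assert_allclose(got.data, ref.data, atol=1e-8)


class TestPatristic:
    def test_toy_values(self, toy_tree):
        pdm = patristic_distances(toy_tree)
        assert pdm.loc["A", "B"] == pytest.approx(2.0)
        assert pdm.loc["A", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(pdm.to_numpy()), 0.0)

    def test_against_dendropy_oracle(self):
        for seed in range(5):
            tree = build_phylogeny(24, 1.0, seed=seed)
            pdm = patristic_distances(tree)
            oracle = tree.phylogenetic_distance_matrix()
            for t1 in tree.taxon_namespace:
                for t2 in tree.taxon_namespace:
                    assert pdm.loc[t1.label, t2.label] == pytest.approx(
                        oracle.patristic_distance(t1, t2), abs=1e-9
                    )

    def test_triangle_inequality(self):
        for seed in range(20):
            tree = build_phylogeny(10, 1.0, seed=seed)
            d = patristic_distances(tree).to_numpy()
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    assert (d[i, :] + d[:, j] >= d[i, j] - 1e-9).all()


class TestNMDS:
    def test_perfect_embedding_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(12)])
        out = nmds(d, k=2, n_starts=8, seed=3)
        assert out.stress < 1e-3

    def test_regular_simplex_has_positive_stress(self):
        # 4 equidistant points cannot embed exactly in the plane
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        out = nmds(d, k=2, n_starts=10, seed=1)
        assert out.stress > 1e-4

    def test_k_must_be_smaller_than_n(self):
        d = DistanceMatrix(np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError):
            nmds(d, k=3)


def test_shannon_per_sample_matches_columns():
    m = CommunityMatrix(pd.DataFrame({"x": [1, 1, 2], "y": [5, 0, 0]}))
    out = shannon_per_sample(m)
    assert out["x"] == pytest.approx(1.0397, abs=1e-4)
    assert out["y"] == 0.0
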