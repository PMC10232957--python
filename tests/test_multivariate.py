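"""Correlation, PCA, Gower distance and Ward.D2 clustering."""

import numpy as np
import pandas as pd
import pytest

from agt_screen.errors import ValidationError
from agt_screen.multivariate import (
    AG_TRAITS, DistanceMatrix, cluster_profile, correlation_matrix,
    gower_distance, pca, ward_d2_cluster, within_between_distances,
)
from agt_screen.traits import TRAIT_ORDER

TRAITS = list(TRAIT_ORDER)


class TestCorrelation:
    def test_panel_headline_correlations(self, panel):
        res = correlation_matrix(panel, TRAITS)
        assert res.r.loc["AGP", "AVI"] == pytest.approx(0.96, abs=0.01)
        assert res.r.loc["SL", "RL"] == pytest.approx(0.72, abs=0.02)
        assert res.stars.loc["AGP", "AVI"] == "***"

    def test_matrix_structure(self, panel):
        res = correlation_matrix(panel, TRAITS)
        R = res.r.to_numpy()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.abs(R).max() <= 1 + 1e-12
        assert np.linalg.eigvalsh(R).min() > -1e-10  # PSD to tolerance

    def test_row_order_invariance(self, panel):
        res1 = correlation_matrix(panel, TRAITS)
        shuffled = panel.sample(frac=1.0, random_state=4)
        res2 = correlation_matrix(shuffled, TRAITS)
        assert np.allclose(res1.r, res2.r)

    def test_constant_trait_flagged(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        res = correlation_matrix(frame, ["a", "b"])
        assert res.constant_traits == ["b"]
        assert np.isnan(res.r.loc["a", "b"])


class TestPca:
    def test_panel_leading_component(self, panel):
        res = pca(panel, TRAITS)
        assert res.eigenvalues[0] == pytest.approx(4.69, abs=0.05)
        assert res.percent_variance[0] == pytest.approx(33.53, abs=0.5)
        assert res.n_components_eigen_gt1 == 5

    def test_eigenvalue_sum_is_trait_count(self, panel):
        res = pca(panel, TRAITS)
        assert res.eigenvalues.sum() == pytest.approx(14.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_cos2_structure(self, panel):
        res = pca(panel, TRAITS)
        # each component's cos2 column sums to its eigenvalue
        assert np.allclose(res.cos2.sum(axis=0), res.eigenvalues, atol=1e-9)
        # each trait's cos2 over all components sums to 1
        assert np.allclose(res.cos2.sum(axis=1), 1.0, atol=1e-9)

    def test_vigor_index_dominates_pc1(self, panel):
        res = pca(panel, TRAITS)
        assert res.cos2["PC1"].idxmax() == "AVI"
        assert res.cos2.loc["AVI", "PC1"] == pytest.approx(0.89, abs=0.02)

    def test_rank_one_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        frame = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca(frame, ["a", "b"])
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)

    def test_row_order_invariance(self, panel):
        res1 = pca(panel, TRAITS)
        res2 = pca(panel.sample(frac=1.0, random_state=1), TRAITS)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues)
        assert np.allclose(res1.cos2, res2.cos2)

    def test_constant_trait_named(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValidationError, match="b"):
            pca(frame, ["a", "b"])


class TestGower:
    def test_hand_arithmetic_single_trait(self):
        frame = pd.DataFrame({"x": [0.0, 5.0, 10.0]}, index=["a", "b", "c"])
        d = gower_distance(frame, ["x"])
        assert d[("a", "c")] == pytest.approx(1.0)
        assert d[("a", "b")] == pytest.approx(0.5)

    def test_identical_genotypes(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 4.0], "y": [2.0, 2.0, 9.0]},
                             index=["a", "b", "c"])
        d = gower_distance(frame, ["x", "y"])
        assert d[("a", "b")] == pytest.approx(0.0)

    def test_opposite_extremes_distance_one(self):
        frame = pd.DataFrame(
            {"x": [0.0, 10.0, 5.0], "y": [1.0, 3.0, 2.0]},
            index=["lo", "hi", "mid"],
        )
        d = gower_distance(frame, ["x", "y"])
        assert d[("lo", "hi")] == pytest.approx(1.0)
        assert np.all((d.matrix >= 0) & (d.matrix <= 1 + 1e-12))

    def test_affine_rescaling_invariance(self, panel):
        d1 = gower_distance(panel, list(AG_TRAITS))
        rescaled = panel.copy()
        rescaled["AGP"] = rescaled["AGP"] * 3.7 + 11.0
        d2 = gower_distance(rescaled, list(AG_TRAITS))
        assert np.allclose(d1.matrix, d2.matrix)

    def test_zero_range_trait_excluded_with_warning(self):
        frame = pd.DataFrame({"x": [0.0, 1.0], "y": [2.0, 2.0]},
                             index=["a", "b"])
        with pytest.warns(UserWarning, match="y"):
            d = gower_distance(frame, ["x", "y"])
        assert d[("a", "b")] == pytest.approx(1.0)


def lance_williams_ward(D: np.ndarray):
    """Tiny independent Ward.D2 agglomerator (naive O(n^3))."""
    n = D.shape[0]
    active = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    while len(active) > 1:
        (a, b), h = min(
            (((x, y), d[frozenset((x, y))])
             for x in active for y in active if x < y),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        na, nb = len(active[a]), len(active[b])
        merged = active[a] + active[b]
        for l in list(active):
            if l in (a, b):
                continue
            nl = len(active[l])
            dal, dbl = d[frozenset((a, l))], d[frozenset((b, l))]
            dab = d[frozenset((a, b))]
            new = np.sqrt(
                ((na + nl) * dal**2 + (nb + nl) * dbl**2 - nl * dab**2)
                / (na + nb + nl)
            )
            d[frozenset((a, l))] = new
        del active[b]
        active[a] = merged
        d = {k: v for k, v in d.items() if b not in k}
    return heights


class TestWardClustering:
    def test_merge_heights_match_independent_agglomerator(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"g{i}" for i in range(9)], D, "euclidean")
        tree, _ = ward_d2_cluster(dm)
        expected = lance_williams_ward(D)
        assert np.allclose(sorted(tree.heights), sorted(expected))

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (15, 3)),
                       rng.normal(10, 0.3, (15, 3))])
        frame = pd.DataFrame(X, columns=["a", "b", "c"],
                             index=[f"g{i}" for i in range(30)])
        d = gower_distance(frame, ["a", "b", "c"])
        _, assign = ward_d2_cluster(d, k=2)
        first, second = assign.iloc[:15], assign.iloc[15:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_heights_monotone_on_panel(self, panel):
        d = gower_distance(panel, list(AG_TRAITS))
        tree, _ = ward_d2_cluster(d)
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_assignments_nested_refinements(self, panel):
        d = gower_distance(panel, list(AG_TRAITS))
        tree, _ = ward_d2_cluster(d)
        prev = tree.assignments(5)
        nxt = tree.assignments(6)
        # every k=6 cluster sits inside exactly one k=5 cluster
        mapping = pd.crosstab(nxt, prev)
        assert ((mapping > 0).sum(axis=1) == 1).all()

    def test_k_equals_n(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=list("abc"))
        d = gower_distance(frame, ["x"])
        _, assign = ward_d2_cluster(d, k=3)
        assert assign.nunique() == 3

    def test_k_out_of_range(self):
        frame = pd.DataFrame({"x": [0.0, 1.0]}, index=list("ab"))
        d = gower_distance(frame, ["x"])
        tree, _ = ward_d2_cluster(d)
        with pytest.raises(ValidationError):
            tree.assignments(5)

    def test_tolerant_quartet_coclusters(self, panel):
        d = gower_distance(panel, list(AG_TRAITS))
        _, assign = ward_d2_cluster(d, k=6)
        quartet = ["Karuthakar", "Poovan samba", "Mattaikar", "Edakkal"]
        assert assign[quartet].nunique() == 1

    def test_newick_export_parses(self, panel):
        d = gower_distance(panel.iloc[:10], list(AG_TRAITS))
        tree, _ = ward_d2_cluster(d)
        nw = tree.to_newick()
        assert nw.endswith(";") and nw.count("(") == 9


class TestClusterProfile:
    def test_identical_points_zero_distances(self):
        frame = pd.DataFrame({"x": [1.0] * 4, "y": [2.0] * 4},
                             index=list("abcd"))
        d = DistanceMatrix(list("abcd"), np.zeros((4, 4)), "gower")
        assign = pd.Series([1, 1, 2, 2], index=list("abcd"))
        within, between = within_between_distances(assign, d)
        assert (within == 0).all()
        assert (between.to_numpy() == 0).all()

    def test_between_distance_equals_brute_force(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = [f"g{i}" for i in range(8)]
        d = DistanceMatrix(labels, D, "euclidean")
        assign = pd.Series([1] * 4 + [2] * 4, index=labels)
        _, between = within_between_distances(assign, d)
        brute = np.mean([D[i, j] for i in range(4) for j in range(4, 8)])
        assert between.loc[1, 2] == pytest.approx(brute)

    def test_imposed_tolerant_cluster_mean(self, scored):
        """Imposing the published tolerant-quartet membership reproduces
        the published cluster AGP mean."""
        quartet = ["Karuthakar", "Poovan samba", "Mattaikar", "Edakkal"]
        assign = pd.Series(
            [4 if g in quartet else 1 for g in scored.index],
            index=scored.index,
        )
        profile = cluster_profile(assign, scored, traits=["AGP"])
        summary = profile["summary"].set_index("group")
        assert summary.loc["4", "mean"] == pytest.approx(97.50, abs=0.01)

    def test_singleton_cluster_flagged(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 2.0]}, index=list("abc"))
        d = gower_distance(frame, ["x"])
        assign = pd.Series([1, 1, 2], index=list("abc"))
        profile = cluster_profile(assign, frame, traits=["x"], distances=d)
        assert profile["within"][2] == 0.0
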