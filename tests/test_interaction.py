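"""Neighbour graphs, enrichment features, the niche classifier and metrics."""

import numpy as np
import pytest

import nichecov as nc
from nichecov.interaction import (
    InteractionModel,
    build_interaction_graph,
    build_neighborhoods,
    domain_consistency,
    enrichment_features,
    fit_niche_classifier,
)


# ---------------------------------------------------------------------------
# neighbourhoods
# ---------------------------------------------------------------------------

class TestNeighborhoods:
    def test_collinear_points_radius_mode(self):
        coords = np.array([[0.0, 0.0], [3.0, 0.0], [6.0, 0.0]])
        g = build_neighborhoods(coords, "radius_R", R=5.0)
        assert len(g.neighbors(1)) == 2
        assert len(g.neighbors(0)) == 1

    def test_delaunay_edge_beyond_max_dist_discarded(self):
        # square of side 30 plus one far-away cell: Delaunay connects it,
        # but the 150-unit edges exceed the 100-unit cutoff
        coords = np.array(
            [[0, 0], [30, 0], [0, 30], [30, 30], [180.0, 15.0]], dtype=float
        )
        g = build_neighborhoods(coords, "delaunay_R0", max_dist=100.0)
        assert len(g.neighbors(4)) == 0
        assert len(g.neighbors(0)) >= 2

    def test_radius_mode_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 50, (200, 2))
        R = 6.0
        g = build_neighborhoods(coords, "radius_R", R=R)
        d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        brute = (d <= R) & ~np.eye(200, dtype=bool)
        mine = g.adjacency.toarray() > 0
        np.testing.assert_array_equal(mine, brute)

    def test_adjacency_symmetric_no_self_edges(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 50, (100, 2))
        g = build_neighborhoods(coords, "delaunay_R0")
        a = g.adjacency
        assert (a != a.T).nnz == 0
        assert a.diagonal().sum() == 0

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            build_neighborhoods(np.zeros((3, 2)), "delaunay_R0")


# ---------------------------------------------------------------------------
# enrichment features
# ---------------------------------------------------------------------------

def _chain_graph(labels, edges):
    import scipy.sparse as sp

    n = len(labels)
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return nc.NeighborGraph(adj, "radius_R", 1.0, 1.0)


class TestEnrichment:
    def test_hand_example(self):
        # one central cell with neighbour counts (2, 1) and f = (0.5, 0.5)
        labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        edges = [(0, 1), (0, 2), (0, 3)]
        feat = enrichment_features(_chain_graph(labels, edges), labels)
        row = feat.X[feat.cell_index == 0][0]
        np.testing.assert_allclose(row, [4 / 3, 2 / 3])

    def test_composition_equal_to_global_gives_ones(self):
        labels = np.array(["A", "B", "A", "B"], dtype=object)
        edges = [(0, 1), (0, 2)]  # cell 0 sees one A, one B; f = (0.5, 0.5)
        feat = enrichment_features(_chain_graph(labels, edges), labels)
        row = feat.X[feat.cell_index == 0][0]
        np.testing.assert_allclose(row, [1.0, 1.0])

    def test_algebraic_identity(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 40, (150, 2))
        labels = rng.choice(["A", "B", "C"], 150).astype(object)
        g = build_neighborhoods(coords, "radius_R", R=6.0)
        feat = enrichment_features(g, labels)
        lhs = (feat.f[None, :] * feat.X).sum(axis=1) * feat.Lambda.sum(axis=1)
        rhs = feat.Lambda.sum(axis=1)
        np.testing.assert_allclose(lhs, rhs)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 40, (120, 2))
        labels = rng.choice(["A", "B", "C"], 120).astype(object)
        g = build_neighborhoods(coords, "radius_R", R=7.0)
        feat = enrichment_features(g, labels)
        types = list(feat.type_names)
        f = np.array([np.mean(labels == t) for t in types])
        d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        for row, i in enumerate(feat.cell_index):
            nbrs = np.flatnonzero((d[i] <= 7.0) & (np.arange(120) != i))
            lam = np.array([np.sum(labels[nbrs] == t) for t in types], float)
            np.testing.assert_array_equal(feat.Lambda[row], lam)
            np.testing.assert_allclose(feat.X[row], lam / (f * lam.sum()), atol=1e-9)

    def test_nm_cells_excluded(self):
        labels = np.array(["A", "NM", "B", "A"], dtype=object)
        edges = [(0, 1), (0, 2), (1, 3)]
        feat = enrichment_features(_chain_graph(labels, edges), labels)
        assert "NM" not in feat.type_names
        assert 1 not in feat.cell_index
        # cell 0's NM neighbour does not count
        assert feat.Lambda[feat.cell_index == 0].sum() == 1


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class TestClassifier:
    def test_no_signal_confusion_near_uniform(self):
        rng = np.random.default_rng(0)
        n, k = 600, 3
        conf = np.zeros((k, k))
        n_seeds = 10
        for seed in range(n_seeds):
            X = rng.normal(size=(n, k))
            y = np.repeat(np.arange(k), n // k)
            feat = nc.NicheFeatures(
                np.ones_like(X), X, y, np.full(k, 1 / k),
                np.array([f"T{i}" for i in range(k)], object), np.arange(n),
            )
            model = fit_niche_classifier(feat, seed=seed)
            conf += model.confusion
        conf /= n_seeds
        # each entry within 3 SE of 1/k (SE of a binomial mean over
        # n/k held-out cells per class and n_seeds seeds)
        se = np.sqrt((1 / k) * (1 - 1 / k) / (n / k * n_seeds))
        assert np.all(np.abs(conf - 1 / k) < 3 * se + 0.02)

    def test_constructed_signal_recovered(self):
        # type A cells always have type B neighbours; others see uniform niches
        rng = np.random.default_rng(1)
        n_per = 120
        lam_rows, y = [], []
        for t in range(3):
            for _ in range(n_per):
                if t == 0:
                    lam = np.array([1.0, 6.0, 1.0])
                else:
                    lam = rng.multinomial(8, [1 / 3] * 3).astype(float)
                lam_rows.append(lam)
                y.append(t)
        Lam = np.vstack(lam_rows)
        y = np.array(y)
        f = np.full(3, 1 / 3)
        X = Lam / (f[None] * Lam.sum(1, keepdims=True))
        feat = nc.NicheFeatures(
            Lam, X, y, f, np.array(["A", "B", "C"], object), np.arange(len(y))
        )
        model = fit_niche_classifier(feat, seed=0)
        ia, ib = 0, 1
        assert np.argmax(model.beta[ia]) == ib

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        feat = nc.NicheFeatures(
            np.abs(X), X, y, np.array([0.5, 0.5]),
            np.array(["A", "B"], object), np.arange(200),
        )
        m1 = fit_niche_classifier(feat, seed=9)
        m2 = fit_niche_classifier(feat, seed=9)
        np.testing.assert_array_equal(m1.beta, m2.beta)
        assert m1.C == m2.C

    def test_confusion_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 2))
        y = rng.integers(0, 2, 150)
        feat = nc.NicheFeatures(
            np.abs(X), X, y, np.array([0.5, 0.5]),
            np.array(["A", "B"], object), np.arange(150),
        )
        model = fit_niche_classifier(feat, seed=0)
        np.testing.assert_allclose(model.confusion.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

def _model_from_beta(beta):
    beta = np.asarray(beta, dtype=float)
    k = beta.shape[0]
    names = np.array([f"T{i}" for i in range(k)], object)
    return InteractionModel(
        beta, np.zeros_like(beta), np.zeros(k), np.eye(k), 1.0, 5, names, np.ones(k)
    )


class TestInteractionGraph:
    def test_cutoff_one_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        g = build_interaction_graph(_model_from_beta(rng.normal(size=(4, 4))), 1.0)
        assert g.graph.number_of_edges() == 0

    def test_hand_normalisation(self):
        beta = np.array([[0.4, -0.2, 0.8], [0, 0, 0], [0, 0, 0]])
        g = build_interaction_graph(_model_from_beta(beta), 0.01)
        w = {(u, v): d["weight"] for u, v, d in g.graph.edges(data=True)}
        assert w[("T0", "T0")] == pytest.approx(0.5)
        assert w[("T2", "T0")] == pytest.approx(1.0)
        assert ("T1", "T0") not in w  # negative coefficient excluded

    def test_zero_row_gives_no_edges(self):
        beta = np.array([[0.0, 0.0], [1.0, 0.5]])
        g = build_interaction_graph(_model_from_beta(beta), 0.01)
        assert not any(v == "T0" for _, v in g.graph.edges())


# ---------------------------------------------------------------------------
# domain consistency
# ---------------------------------------------------------------------------

class TestDomainScore:
    def test_identical_compositions_give_zero_z(self):
        domains = np.array(["d1"] * 4 + ["d2"] * 4, object)
        types = np.array(["A", "A", "B", "B"] * 2, object)
        with pytest.warns(UserWarning):
            score, _ = domain_consistency(domains, types)
        np.testing.assert_array_equal(score.Z, 0.0)

    def test_hand_two_by_two(self):
        # f = [[0.8, 0.2], [0.2, 0.8]] -> Z = [[1, -1], [-1, 1]] (population sd)
        domains = np.array(["d1"] * 10 + ["d2"] * 10, object)
        types = np.array(["A"] * 8 + ["B"] * 2 + ["A"] * 2 + ["B"] * 8, object)
        score, _ = domain_consistency(domains, types)
        np.testing.assert_allclose(score.Z, [[1, -1], [-1, 1]], atol=1e-12)

    def test_global_composition_gives_ratio_one(self):
        domains = np.array(["d1"] * 4 + ["d2"] * 4, object)
        types = np.array(["A", "A", "B", "B"] * 2, object)
        with pytest.warns(UserWarning):
            score, _ = domain_consistency(domains, types)
        np.testing.assert_allclose(score.ratio, 1.0)

    def test_best_match_picks_matching_profile(self):
        domains = np.array(["d1"] * 10 + ["d2"] * 10, object)
        types = np.array(["A"] * 8 + ["B"] * 2 + ["A"] * 2 + ["B"] * 8, object)
        profiles = np.array([[1.0, -1.0], [-1.0, 1.0]])
        _, best = domain_consistency(domains, types, profiles)
        np.testing.assert_allclose(best, 1.0)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

class TestEvaluation:
    def test_identical_labelings(self):
        labs = np.array(["A", "B", "A", "C"], object)
        out = nc.evaluate_annotation(labs, labs)
        assert out["ARI"] == pytest.approx(1.0)
        assert out["Jaccard"] == pytest.approx(1.0)

    def test_ari_invariant_under_renaming(self):
        truth = np.array(["A", "A", "B", "B"], object)
        pred = np.array(["B", "B", "A", "A"], object)
        out = nc.evaluate_annotation(pred, truth)
        assert out["ARI"] == pytest.approx(1.0)
        assert out["Jaccard"] == pytest.approx(0.0)

    def test_ari_matches_pair_counting_formula(self):
        truth = np.array(["A", "A", "B", "B", "C", "C"], object)
        pred = np.array(["A", "A", "A", "B", "B", "C"], object)
        # brute-force pair counting over all 15 pairs
        from itertools import combinations

        n = len(truth)
        a = b = c = d = 0
        for i, j in combinations(range(n), 2):
            st, sp_ = truth[i] == truth[j], pred[i] == pred[j]
            a += st and sp_
            b += st and not sp_
            c += (not st) and sp_
            d += (not st) and not sp_
        expected_index = a
        n_pairs = a + b + c + d
        exp = (a + b) * (a + c) / n_pairs
        mx = ((a + b) + (a + c)) / 2
        ari_brute = (expected_index - exp) / (mx - exp)
        out = nc.evaluate_annotation(pred, truth)
        assert out["ARI"] == pytest.approx(ari_brute, abs=1e-9)

    def test_no_shared_names_raises(self):
        with pytest.raises(ValueError):
            nc.evaluate_annotation(
                np.array(["X", "X"], object), np.array(["A", "B"], object)
            )
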