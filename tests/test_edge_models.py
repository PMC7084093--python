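import numpy as np
import pytest

from triaudit import (
    EdgeProbabilityModel,
    SignedEmbedding,
    UndirectedGraph,
    edge_probability,
    expected_degrees,
    fit_lrdp,
    fit_lrhp,
    fit_softmax,
    rdpg_vectors,
    sample_graph,
    spectral_embedding,
    tdp_model,
)

from conftest import complete_graph, random_graph


def _embedding_with_scores(scores: np.ndarray) -> SignedEmbedding:
    """Embedding whose score matrix equals the given symmetric matrix."""
    lam, psi = np.linalg.eigh(scores)
    order = np.argsort(-np.abs(lam))
    lam, psi = lam[order], psi[:, order]
    return SignedEmbedding(psi * np.sqrt(np.abs(lam)), np.where(lam < 0, -1.0, 1.0))


@pytest.fixture(scope="module")
def fixture_pair():
    """A seeded RDPG graph (n=200) with the embedding that generated it."""
    emb, _ = rdpg_vectors(200, 8, "spherical", seed=1)
    graph = sample_graph(tdp_model(emb), 7)
    return emb, graph


class TestTDP:
    def test_clamps_above_one(self):
        emb = _embedding_with_scores(np.array([[0.0, 1.5], [1.5, 0.0]]))
        assert tdp_model(emb).prob(0, 1) == pytest.approx(1.0)

    def test_clamps_below_zero(self):
        emb = _embedding_with_scores(np.array([[0.0, -0.3], [-0.3, 0.0]]))
        assert tdp_model(emb).prob(0, 1) == pytest.approx(0.0)

    def test_interior_passes_through(self):
        emb = _embedding_with_scores(np.array([[0.0, 0.42], [0.42, 0.0]]))
        assert tdp_model(emb).prob(0, 1) == pytest.approx(0.42)

    def test_k2_full_rank_certain_edge(self):
        emb = spectral_embedding(complete_graph(2), 2)
        assert edge_probability(tdp_model(emb), 0, 1) == pytest.approx(1.0)


class TestLRDP:
    def test_constant_scores_give_constant_model(self):
        emb = SignedEmbedding(np.ones((20, 3)) * 0.5)
        g = random_graph(20, 0.3, 0)
        model = fit_lrdp(emb, g, seed=1)
        target = 2 * g.m / (20 * 19)
        probs = [model.prob(i, j) for i in range(5) for j in range(i + 1, 6)]
        assert probs == pytest.approx([target] * len(probs), rel=0.01)

    def test_calibrated_edge_count(self, fixture_pair):
        emb, g = fixture_pair
        model = fit_lrdp(emb, g, seed=3)
        _, expected = expected_degrees(model)
        assert abs(expected - g.m) / g.m <= 0.01

    def test_monotone_in_score(self, fixture_pair):
        emb, g = fixture_pair
        model = fit_lrdp(emb, g, seed=3)
        assert model.params["k"] >= 0
        pairs = [(0, 1), (2, 50), (10, 180), (33, 77)]
        scored = sorted((emb.score(i, j), model.prob(i, j)) for i, j in pairs)
        probs = [p for _, p in scored]
        assert probs == sorted(probs)

    def test_k_zero_closed_form(self):
        emb = SignedEmbedding(np.ones((4, 2)))
        model = EdgeProbabilityModel("LRDP", emb, {"L": 0.8, "k": 0.0, "x0": 0.0})
        assert model.prob(0, 1) == pytest.approx(0.4)

    def test_planted_logistic_recovery(self):
        """Graph sampled from a known logistic law: the calibrated expected
        edge count matches the realized count within 1%."""
        rng = np.random.default_rng(5)
        emb = SignedEmbedding(rng.uniform(0, 1, size=(200, 4)))
        scores = emb.score_matrix()
        p_true = 0.9 / (1 + np.exp(-3.0 * (scores - 0.8)))
        np.fill_diagonal(p_true, 0.0)
        iu = np.triu_indices(200, k=1)
        draws = rng.random(len(iu[0])) < p_true[iu]
        edges = {(int(a), int(b)) for a, b, hit in zip(*iu, draws) if hit}
        g = UndirectedGraph(n=200, edges=edges)
        model = fit_lrdp(emb, g, seed=11)
        _, expected = expected_degrees(model)
        assert abs(expected - g.m) / g.m <= 0.01


class TestLRHP:
    def test_tied_weights_reproduce_lrdp(self, fixture_pair):
        emb, _ = fixture_pair
        k, x0, L = 2.5, 0.3, 0.7
        lrdp = EdgeProbabilityModel("LRDP", emb, {"L": L, "k": k, "x0": x0})
        lrhp = EdgeProbabilityModel(
            "LRHP", emb, {"L": L, "w": k * np.ones(emb.d), "b": -k * x0}
        )
        rows = np.arange(0, emb.n, 17)
        assert lrhp.prob_block(rows) == pytest.approx(lrdp.prob_block(rows), abs=1e-9)

    def test_calibrated_edge_count(self, fixture_pair):
        emb, g = fixture_pair
        model = fit_lrhp(emb, g, seed=3)
        _, expected = expected_degrees(model)
        assert abs(expected - g.m) / g.m <= 0.01

    def test_constant_features_give_constant_model(self):
        emb = SignedEmbedding(np.ones((20, 1)))
        g = random_graph(20, 0.25, 2)
        model = fit_lrhp(emb, g, seed=1)
        target = 2 * g.m / (20 * 19)
        assert model.prob(0, 1) == pytest.approx(target, rel=0.01)
        assert model.prob(7, 15) == pytest.approx(target, rel=0.01)


class TestSoftmax:
    def test_identical_vectors_regular_graph(self):
        # 4-regular graph on 8 vertices (circulant), identical vectors
        n, k = 8, 4
        edges = {(i, (i + s) % n) for i in range(n) for s in (1, 2)}
        edges = {(min(a, b), max(a, b)) for a, b in edges}
        g = UndirectedGraph(n=n, edges=edges)
        emb = SignedEmbedding(np.ones((n, 2)))
        model = fit_softmax(emb, g)
        for i, j in [(0, 1), (2, 6), (3, 4)]:
            assert model.prob(i, j) == pytest.approx(k / (n - 1))

    def test_identical_vectors_general_graph(self):
        g = random_graph(30, 0.2, 4)
        deg = g.degrees()
        emb = SignedEmbedding(np.full((30, 3), 0.4))
        model = fit_softmax(emb, g)
        for i, j in [(0, 5), (10, 20), (3, 29)]:
            want = min(1.0, (deg[i] + deg[j]) / (2 * (30 - 1)))
            assert model.prob(i, j) == pytest.approx(want)

    def test_preclamp_row_sums_equal_degrees(self, fixture_pair):
        emb, g = fixture_pair
        model = fit_softmax(emb, g)
        q = model._directed_softmax_block(np.arange(g.n))
        assert np.abs(q.sum(axis=1) - g.degrees()).max() < 1e-9

    def test_isolated_vertex_row_is_zero(self):
        g = UndirectedGraph(n=4, edges={(0, 1), (1, 2), (0, 2)})
        emb = SignedEmbedding(np.random.default_rng(0).uniform(0, 1, (4, 2)))
        model = fit_softmax(emb, g)
        q = model._directed_softmax_block(np.array([3]))
        assert q == pytest.approx(np.zeros((1, 4)))

    def test_expected_edges_at_most_observed(self, fixture_pair):
        emb, g = fixture_pair
        model = fit_softmax(emb, g)
        _, expected = expected_degrees(model)
        assert expected <= g.m + 1e-6


@pytest.fixture(scope="module")
def all_models():
    emb, _ = rdpg_vectors(60, 5, "spherical", seed=9)
    g = sample_graph(tdp_model(emb), 13)
    return [
        tdp_model(emb),
        fit_lrdp(emb, g, seed=2),
        fit_lrhp(emb, g, seed=2),
        fit_softmax(emb, g),
    ]


class TestModelContracts:
    def test_symmetry_range_zero_diagonal(self, all_models):
        for model in all_models:
            p = model.prob_block(np.arange(model.n))
            assert np.all(p >= 0) and np.all(p <= 1)
            assert p == pytest.approx(p.T, abs=1e-12)
            assert np.all(np.diag(p) == 0)

    def test_edge_probability_symmetric_accessor(self, all_models):
        for model in all_models:
            assert edge_probability(model, 3, 41) == pytest.approx(
                edge_probability(model, 41, 3)
            )
        with pytest.raises(IndexError):
            edge_probability(all_models[0], 2, 2)

    def test_expected_degrees_blockwise_consistency(self, all_models):
        for model in all_models:
            exp_deg, exp_edges = expected_degrees(model)
            dense = model.prob_block(np.arange(model.n))
            assert exp_deg == pytest.approx(dense.sum(axis=1))
            assert exp_edges == pytest.approx(dense.sum() / 2)


def test_expected_degrees_exact_at_full_rank():
    """Full-rank TDP reproduces the adjacency, so expected degrees are the
    true degrees exactly."""
    g = random_graph(25, 0.3, 1)
    model = tdp_model(spectral_embedding(g, g.n))
    exp_deg, exp_edges = expected_degrees(model)
    assert exp_deg == pytest.approx(g.degrees(), abs=1e-7)
    assert exp_edges == pytest.approx(g.m, abs=1e-6)


def test_constant_half_model_expected_degrees():
    emb = SignedEmbedding(np.full((5, 1), np.sqrt(0.5)))
    exp_deg, _ = expected_degrees(tdp_model(emb))
    assert exp_deg == pytest.approx(np.full(5, 2.0))
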