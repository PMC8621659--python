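import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import litmine as lm
from litmine.lda import LDA
from litmine.corpus import BowCorpus
from litmine.synthgen import GeneratorSpec, gen_corpus
from litmine.viz import (
    _pcoa_2d,
    export_json,
    intertopic_map,
    jensen_shannon,
    relevance,
    saliency,
    sweep_topic_counts,
    topic_summaries,
)


class TestRelevance:
    def test_lambda_one_is_frequency_ranking(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(20))
        p_w = rng.dirichlet(np.ones(20))
        r = relevance(phi, p_w, lam=1.0)
        assert (np.argsort(r) == np.argsort(np.log(phi))).all()

    def test_lambda_zero_is_lift_ranking(self):
        rng = np.random.default_rng(1)
        phi = rng.dirichlet(np.ones(20))
        p_w = rng.dirichlet(np.ones(20))
        r = relevance(phi, p_w, lam=0.0)
        assert (np.argsort(r) == np.argsort(phi / p_w)).all()

    def test_no_lift_is_zero_at_lambda_zero(self):
        assert relevance(0.05, 0.05, lam=0.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        expected = 0.6 * math.log(0.05) + 0.4 * math.log(5.0)
        assert relevance(0.05, 0.01, lam=0.6) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            relevance(0.0, 0.1, 0.5)
        with pytest.raises(ValueError):
            relevance(0.1, 0.1, 1.5)


class TestSaliency:
    def test_zero_when_posterior_equals_prevalence(self):
        prev = np.array([0.3, 0.7])
        assert saliency(0.1, prev, prev) == pytest.approx(0.0)

    def test_exclusive_word_beats_uniform_word(self):
        prev = np.array([0.5, 0.5])
        s_excl = saliency(0.1, np.array([1.0, 0.0]), prev)
        s_unif = saliency(0.1, np.array([0.5, 0.5]), prev)
        assert s_excl > s_unif == pytest.approx(0.0)

    def test_hand_arithmetic_two_topics(self):
        p_w, q, prev = 0.2, np.array([0.8, 0.2]), np.array([0.5, 0.5])
        expected = p_w * (0.8 * math.log(0.8 / 0.5) + 0.2 * math.log(0.2 / 0.5))
        assert saliency(p_w, q, prev) == pytest.approx(expected)


class TestJSD:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_is_ln2(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.3, 0.7])
        assert jensen_shannon(p, q) == pytest.approx(math.log(2))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_symmetry_bounds(self, dim, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(dim))
        q = rng.dirichlet(np.ones(dim))
        d = jensen_shannon(p, q)
        assert d == pytest.approx(jensen_shannon(q, p))
        assert -1e-12 <= d <= math.log(2) + 1e-12


class TestIntertopicMap:
    def _results_with_phi(self, phi):
        K, V = phi.shape
        bow = BowCorpus(docs=[[(w, 1) for w in range(V)]], vocab_size=V)
        res = LDA(bow, K=K, alpha=1.0).fit(n_iter=2, seed=0)
        res.phi = np.asarray(phi, float)
        res.theta = np.full((1, K), 1.0 / K)
        return res

    def test_identical_topics_coincide(self):
        phi = np.tile(np.array([0.2, 0.3, 0.5]), (2, 1))
        tmap = intertopic_map(self._results_with_phi(phi))
        assert tmap.distance_matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tmap.coords[0], tmap.coords[1], atol=1e-6)

    def test_three_topics_distances_preserved(self):
        # 3 points always embed exactly in the plane
        phi = np.array(
            [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]]
        )
        res = self._results_with_phi(phi)
        tmap = intertopic_map(res)
        for i in range(3):
            for j in range(3):
                expected = jensen_shannon(phi[i], phi[j])
                got = np.linalg.norm(tmap.coords[i] - tmap.coords[j])
                assert got == pytest.approx(expected, abs=1e-9)
        assert np.allclose(tmap.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_k1_rejected(self):
        bow = BowCorpus(docs=[[(0, 2)]], vocab_size=1)
        res = LDA(bow, K=1, alpha=1.0).fit(n_iter=2, seed=0)
        with pytest.raises(ValueError, match="one topic"):
            intertopic_map(res)

    def test_pcoa_recovers_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = _pcoa_2d(dist)
        back = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(back, dist, atol=1e-9)


class TestSummariesAndSweep:
    def test_summaries_shape_and_order(self, separable_fit):
        res = separable_fit["results"]
        summaries = topic_summaries(res, n_terms=10)
        assert len(summaries) == res.K
        prevs = [s.prevalence for s in summaries]
        assert sum(prevs) == pytest.approx(1.0)
        for s in summaries:
            assert len(s.top_terms) == 10
            rel = [t[3] for t in s.top_terms]
            assert rel == sorted(rel, reverse=True)

    def test_export_json_schema(self, separable_fit, tmp_path):
        doc = export_json(separable_fit["results"], tmp_path / "viz.json", n_terms=5)
        assert doc["schema_version"] == 1 and len(doc["topics"]) == 3
        assert all(len(t["top_terms"]) == 5 for t in doc["topics"])

    def test_sweep_on_separable_corpus(self):
        spec = GeneratorSpec(
            K_true=5, vocab_size=100, n_docs=80, doc_length_mean=50,
            disjoint_topics=True, alpha_true=0.1, seed=4,
        )
        arts, _ = gen_corpus(spec)
        d = lm.build_dictionary(arts)
        bow = lm.to_bow(arts, d)
        rows = sweep_topic_counts(bow, [5, 20], seed=6, n_iter=200, alpha=0.1)
        at5, at20 = rows[0], rows[1]
        assert at5["evenness"] > 0.9
        assert at5["overlap"] == 0
        assert at20["overlap"] > at5["overlap"]

    def test_sweep_k1_reports_missing(self, separable_fit):
        rows = sweep_topic_counts(separable_fit["bow"], [1], seed=0, n_iter=20)
        assert rows[0]["separation"] is None and rows[0]["overlap"] is None

    def test_sweep_deterministic(self, separable_fit):
        bow = separable_fit["bow"]
        r1 = sweep_topic_counts(bow, [2], seed=3, n_iter=50)
        r2 = sweep_topic_counts(bow, [2], seed=3, n_iter=50)
        assert r1 == r2


class TestPlot:
    def test_topic_map_plot_returns_axes(self, separable_fit):
        import matplotlib

        matplotlib.use("Agg")
        tmap = intertopic_map(separable_fit["results"])
        ax = tmap.plot()
        assert len(ax.collections) == 1  # the circle layer
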