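import numpy as np
import pytest

import litmine as lm
from litmine.corpus import Article
from litmine.expansion import (
    ExpansionConfig,
    doc_similarity,
    filter_candidate,
    run_expansion,
    threshold_sweep,
)
from litmine.synthgen import GeneratorSpec, gen_corpus, gen_candidate_stream

from .oracles import cosine


class TestDocSimilarity:
    def test_identical_documents(self):
        tf = np.array([2.0, 0.0, 1.0])
        th = np.array([0.7, 0.3])
        assert doc_similarity(tf, th, tf, th) == pytest.approx(1.0)

    def test_orthogonal_term_vectors_zero_despite_topics(self):
        th = np.array([0.5, 0.5])
        sim = doc_similarity([1, 0, 0], th, [0, 1, 0], th)
        assert sim == 0.0

    def test_hand_cosine_min_rule(self):
        th = np.array([0.5, 0.5])
        sim = doc_similarity([1, 0, 1], th, [1, 1, 0], th)
        assert sim == pytest.approx(0.5)  # word cosine 0.5, topic cosine 1

    def test_zero_vector_gives_zero(self):
        assert doc_similarity([0, 0], [0.5, 0.5], [1, 0], [0.5, 0.5]) == 0.0

    @pytest.mark.parametrize("mode,expected", [("word", 0.5), ("topic", 1.0)])
    def test_single_clause_modes(self, mode, expected):
        th = np.array([0.5, 0.5])
        sim = doc_similarity([1, 0, 1], th, [1, 1, 0], th, mode=mode)
        assert sim == pytest.approx(expected)


class TestFilterCandidate:
    def _dup_corpus(self, n, V=4):
        tf = np.tile(np.array([1.0, 2.0, 0.0, 1.0]), (n, 1))
        th = np.tile(np.array([0.9, 0.1]), (n, 1))
        return tf, th

    def test_five_duplicates_accept(self):
        tf, th = self._dup_corpus(5)
        cfg = ExpansionConfig(threshold=0.95, min_matches=5)
        verdict, ev = filter_candidate(tf[0], th[0], tf, th, cfg)
        assert verdict == "accept" and ev["n_matches"] == 5

    def test_four_duplicates_reject(self):
        tf, th = self._dup_corpus(4)
        cfg = ExpansionConfig(threshold=0.95, min_matches=5)
        verdict, _ = filter_candidate(tf[0], th[0], tf, th, cfg)
        assert verdict == "reject"

    def test_brute_force_oracle_on_random_candidates(self):
        rng = np.random.default_rng(42)
        n_acc, V, K = 30, 12, 3
        acc_tf = rng.poisson(2.0, size=(n_acc, V)).astype(float)
        acc_th = rng.dirichlet(np.ones(K), size=n_acc)
        cfg = ExpansionConfig(threshold=0.6, min_matches=3)
        for _ in range(100):
            c_tf = rng.poisson(2.0, size=V).astype(float)
            c_th = rng.dirichlet(np.ones(K))
            verdict, ev = filter_candidate(c_tf, c_th, acc_tf, acc_th, cfg)
            # independent all-pairs recomputation
            sims = [
                min(cosine(c_tf, acc_tf[i]), cosine(c_th, acc_th[i]))
                for i in range(n_acc)
            ]
            n_matches = sum(s >= cfg.threshold for s in sims)
            expected = "accept" if n_matches >= cfg.min_matches else "reject"
            assert verdict == expected and ev["n_matches"] == n_matches

    def test_monotonicity_in_threshold_and_min_matches(self):
        rng = np.random.default_rng(3)
        acc_tf = rng.poisson(2.0, size=(20, 10)).astype(float)
        acc_th = rng.dirichlet(np.ones(3), size=20)
        cands = [
            (rng.poisson(2.0, size=10).astype(float), rng.dirichlet(np.ones(3)))
            for _ in range(50)
        ]

        def accepted(threshold, min_matches):
            cfg = ExpansionConfig(threshold=threshold, min_matches=min_matches)
            return {
                i
                for i, (tf, th) in enumerate(cands)
                if filter_candidate(tf, th, acc_tf, acc_th, cfg)[0] == "accept"
            }

        for lo, hi in [(0.3, 0.5), (0.5, 0.7), (0.7, 0.95)]:
            assert accepted(hi, 3) <= accepted(lo, 3)
        for m in [1, 2, 4, 8]:
            assert accepted(0.5, m + 1) <= accepted(0.5, m)


@pytest.fixture(scope="module")
def stream_setup():
    spec = GeneratorSpec(
        K_true=4, vocab_size=80, n_docs=60, doc_length_mean=60,
        alpha_true=0.05, disjoint_topics=True, offdomain_fraction=0.3, seed=11,
    )
    seeds, truth = gen_corpus(spec)
    cands, labels = gen_candidate_stream(spec, truth, n_candidates=60)
    dictionary = lm.build_dictionary(seeds)
    return spec, seeds, truth, cands, labels, dictionary


class TestRunExpansion:
    def test_empty_stream_returns_seed_unchanged(self, stream_setup):
        _, seeds, _, _, _, d = stream_setup
        final, log, _ = run_expansion(seeds, [], d, ExpansionConfig(), K=4, seed=0)
        assert final == seeds and log.candidates == [] and log.cycles == []

    def test_disjoint_vocabulary_all_rejected(self, stream_setup):
        _, seeds, _, _, _, d = stream_setup
        cands = [
            Article(id=f"X{i}", title="t", abstract="zzz", tokens=["zzzz"] * 10)
            for i in range(10)
        ]
        cfg = ExpansionConfig(threshold=0.5, min_matches=5, batch_size=5,
                              n_iter_refit=50, n_iter_fold_in=50)
        final, log, _ = run_expansion(seeds, cands, d, cfg, K=4, seed=1, alpha=0.1)
        assert len(final) == len(seeds)
        assert all(c.verdict == "reject" for c in log.candidates)

    def test_seed_copies_accepted(self, stream_setup):
        _, seeds, _, _, _, d = stream_setup
        copies = [
            Article(id=f"copy{i}", title=a.title, abstract=a.abstract,
                    tokens=list(a.tokens))
            for i, a in enumerate(seeds[:10])
        ]
        cfg = ExpansionConfig(threshold=0.999, min_matches=1, batch_size=10,
                              refit_each_cycle=False, n_iter_refit=100,
                              n_iter_fold_in=100)
        final, log, _ = run_expansion(seeds, copies, d, cfg, K=4, seed=2, alpha=0.1)
        assert all(c.verdict == "accept" for c in log.candidates)
        assert len(final) == len(seeds) + 10

    def test_log_complete_and_corpus_monotone(self, stream_setup):
        _, seeds, _, cands, _, d = stream_setup
        cfg = ExpansionConfig(threshold=0.5, min_matches=5, batch_size=20,
                              n_iter_refit=80, n_iter_fold_in=80)
        final, log, _ = run_expansion(seeds, cands, d, cfg, K=4, seed=3, alpha=0.1)
        assert sorted(c.id for c in log.candidates) == sorted(c.id for c in cands)
        sizes = [c.corpus_size_after for c in log.cycles]
        assert sizes == sorted(sizes)
        assert len(final) == len(seeds) + log.n_accepted

    def test_within_cycle_order_invariance(self, stream_setup):
        _, seeds, _, cands, _, d = stream_setup
        batch = cands[:20]
        cfg = ExpansionConfig(threshold=0.5, min_matches=5, batch_size=20,
                              n_iter_refit=80, n_iter_fold_in=200)
        _, log_fwd, _ = run_expansion(seeds, batch, d, cfg, K=4, seed=4, alpha=0.1)
        _, log_rev, _ = run_expansion(seeds, batch[::-1], d, cfg, K=4, seed=4, alpha=0.1)
        fwd = {c.id: c.verdict for c in log_fwd.candidates}
        rev = {c.id: c.verdict for c in log_rev.candidates}
        assert fwd == rev

    def test_log_csv_round_trip(self, stream_setup, tmp_path):
        _, seeds, _, cands, _, d = stream_setup
        cfg = ExpansionConfig(threshold=0.5, min_matches=5, batch_size=30,
                              n_iter_refit=80, n_iter_fold_in=80)
        _, log, _ = run_expansion(seeds, cands[:30], d, cfg, K=4, seed=5, alpha=0.1)
        log.to_csv(tmp_path / "log.csv")
        log.to_json(tmp_path / "log.json")
        lines = (tmp_path / "log.csv").read_text().strip().splitlines()
        assert len(lines) == 1 + len(log.candidates)


class TestThresholdSweep:
    def test_acceptance_counts_monotone(self):
        rng = np.random.default_rng(0)
        sims = [rng.random(20) for _ in range(40)]
        rows = threshold_sweep(sims, [0.1, 0.5, 0.9], min_matches=5)
        counts = [r["n_accepted"] for r in rows]
        assert counts == sorted(counts, reverse=True)


class TestShippedConfig:
    def test_default_config_yaml_loads(self):
        from importlib import resources

        import yaml

        text = resources.files("litmine.data").joinpath(
            "default_config.yaml"
        ).read_text()
        cfg = yaml.safe_load(text)
        econf = ExpansionConfig(**cfg["expansion"])
        assert econf.threshold == 0.95
        assert econf.min_matches == 5
        assert econf.batch_size == 100

    def test_query_clauses_shipped(self):
        from importlib import resources

        import yaml

        text = resources.files("litmine.data").joinpath(
            "model1_queries.yaml"
        ).read_text()
        queries = yaml.safe_load(text)["queries"]
        assert len(queries) == 8
        assert all(isinstance(q, str) and q for q in queries)
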