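"""Seeded corpus expansion by a similarity-threshold acceptance rule.

Starting from an accepted seed corpus and a fitted topic model, candidate
articles arrive in batches (one batch per training cycle, default 100). A
candidate is accepted only if it is at least ``threshold``-similar (default
0.95) to at least ``min_matches`` (default 5) articles already in the
accepted corpus. Accepted candidates join the corpus; the topic model is
refitted on the enlarged corpus at the end of each cycle (configurable), so
the model is progressively refined as the corpus grows.

Document similarity combines two views of a document — its word-frequency
vector and its (folded-in) topic distribution. The acceptance sentence
requires similarity "in frequency of words and topics", read here as a
conjunction: the reported similarity is the minimum of the two cosine
similarities, so both clauses must clear the threshold. Either clause alone
can be selected via ``ExpansionConfig.mode``.

Within a cycle, every candidate is judged against the corpus as it stood at
the start of the cycle, never against co-batch acceptances, so verdicts do
not depend on the order of candidates inside a batch.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Article, BowCorpus, Dictionary, bow_vector, to_bow
from .lda import LDA, LDAResults

__all__ = [
    "ExpansionConfig",
    "ExpansionLog",
    "doc_similarity",
    "filter_candidate",
    "run_expansion",
]


@dataclass
class ExpansionConfig:
    """Constants of the expansion rule.

    threshold: similarity cut-off in (0, 1]; min_matches: accepted articles
    that must clear it; batch_size: candidates per training cycle;
    mode: 'min' (both word and topic cosines must pass), 'word' or 'topic'.
    """

    threshold: float = 0.95
    min_matches: int = 5
    batch_size: int = 100
    refit_each_cycle: bool = True
    mode: str = "min"
    n_iter_refit: int = 300
    n_iter_fold_in: int = 200

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.mode not in ("min", "word", "topic"):
            raise ValueError(f"mode must be min|word|topic, got {self.mode!r}")


@dataclass
class CandidateRecord:
    id: str
    cycle: int
    max_sim: float
    n_matches: int
    verdict: str  # accept | reject


@dataclass
class CycleRecord:
    cycle: int
    n_candidates: int
    n_accepted: int
    corpus_size_after: int
    refit: bool


@dataclass
class ExpansionLog:
    candidates: list[CandidateRecord] = field(default_factory=list)
    cycles: list[CycleRecord] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(1 for c in self.candidates if c.verdict == "accept")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["candidate_id", "cycle", "max_sim", "n_matches", "verdict"])
            for c in self.candidates:
                w.writerow([c.id, c.cycle, f"{c.max_sim:.6f}", c.n_matches, c.verdict])

    def summary(self) -> dict:
        return {
            "n_candidates": len(self.candidates),
            "n_accepted": self.n_accepted,
            "n_rejected": len(self.candidates) - self.n_accepted,
            "n_cycles": len(self.cycles),
            "cycles": [asdict(c) for c in self.cycles],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def doc_similarity(
    tf_a: np.ndarray,
    theta_a: np.ndarray,
    tf_b: np.ndarray,
    theta_b: np.ndarray,
    mode: str = "min",
) -> float:
    """Similarity in [0, 1] between two documents under the same model.

    ``tf_*`` are term-frequency count vectors over the shared dictionary,
    ``theta_*`` the documents' topic distributions. 'min' requires both the
    word-frequency cosine and the topic cosine (the conjunction reading of
    "similar in frequency of words and topics"); a zero vector on either
    side contributes similarity 0.
    """
    word_sim = _cosine(np.asarray(tf_a, float), np.asarray(tf_b, float))
    topic_sim = _cosine(np.asarray(theta_a, float), np.asarray(theta_b, float))
    if mode == "word":
        return word_sim
    if mode == "topic":
        return topic_sim
    return min(word_sim, topic_sim)


def filter_candidate(
    cand_tf: np.ndarray,
    cand_theta: np.ndarray,
    accepted_tf: np.ndarray,
    accepted_theta: np.ndarray,
    config: ExpansionConfig,
) -> tuple[str, dict]:
    """Accept iff >= min_matches accepted articles are >= threshold similar.

    ``accepted_tf`` is an (n_accepted, V) count matrix, ``accepted_theta``
    (n_accepted, K). Returns the verdict and the similarity evidence.
    """
    if accepted_tf.shape[0] == 0:
        raise ValueError("accepted corpus is empty")
    sims = np.array(
        [
            doc_similarity(
                cand_tf, cand_theta, accepted_tf[i], accepted_theta[i], config.mode
            )
            for i in range(accepted_tf.shape[0])
        ]
    )
    n_matches = int((sims >= config.threshold).sum())
    verdict = "accept" if n_matches >= config.min_matches else "reject"
    return verdict, {"max_sim": float(sims.max()), "n_matches": n_matches}


def _tf_matrix(corpus: BowCorpus) -> np.ndarray:
    return np.asarray(corpus.to_sparse().todense(), dtype=float)


def run_expansion(
    seed_articles: Sequence[Article],
    candidates: Sequence[Article],
    dictionary: Dictionary,
    config: ExpansionConfig | None = None,
    K: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
) -> tuple[list[Article], ExpansionLog, LDAResults]:
    """Grow the accepted corpus from a candidate stream in training cycles.

    All articles must be tokenised against ``dictionary``. Each cycle takes
    the next ``batch_size`` candidates, folds each into the current model,
    applies :func:`filter_candidate` against the pre-cycle accepted corpus,
    appends acceptances, and (by default) refits the model on the enlarged
    corpus. Returns the final accepted articles, the full per-candidate /
    per-cycle log, and the final fitted model. Deterministic given ``seed``.
    """
    config = config or ExpansionConfig()
    accepted = list(seed_articles)
    log = ExpansionLog()

    corpus = to_bow(accepted, dictionary)
    results = LDA(corpus, K=K, alpha=alpha, beta=beta, vocabulary=dictionary.words()).fit(
        n_iter=config.n_iter_refit, seed=seed
    )
    if not candidates:
        return accepted, log, results

    accepted_tf = _tf_matrix(corpus)
    accepted_theta = results.theta.copy()

    n_cycles = (len(candidates) + config.batch_size - 1) // config.batch_size
    for cycle in range(n_cycles):
        batch = candidates[cycle * config.batch_size : (cycle + 1) * config.batch_size]
        new_articles: list[Article] = []
        new_tf: list[np.ndarray] = []
        new_theta: list[np.ndarray] = []
        for cand in batch:
            vec, _ = bow_vector(cand.tokens, dictionary)
            tf = np.zeros(len(dictionary))
            for w, c in vec:
                tf[w] = c
            # fold-in seed derives from the candidate id, not its batch
            # position, so verdicts are invariant to within-cycle order
            cand_seed = zlib.crc32(cand.id.encode())
            theta, _empty = results.fold_in(
                vec,
                n_iter=config.n_iter_fold_in,
                seed=(seed + 7919 * cycle + cand_seed) % 2**31,
            )
            verdict, ev = filter_candidate(tf, theta, accepted_tf, accepted_theta, config)
            log.candidates.append(
                CandidateRecord(
                    id=cand.id,
                    cycle=cycle,
                    max_sim=ev["max_sim"],
                    n_matches=ev["n_matches"],
                    verdict=verdict,
                )
            )
            if verdict == "accept":
                new_articles.append(cand)
                new_tf.append(tf)
                new_theta.append(theta)

        accepted.extend(new_articles)
        refit = bool(config.refit_each_cycle and new_articles)
        if refit:
            corpus = to_bow(accepted, dictionary)
            results = LDA(
                corpus, K=K, alpha=alpha, beta=beta, vocabulary=dictionary.words()
            ).fit(n_iter=config.n_iter_refit, seed=(seed + cycle + 1) % 2**31)
            accepted_tf = _tf_matrix(corpus)
            accepted_theta = results.theta.copy()
        elif new_articles:
            accepted_tf = np.vstack([accepted_tf] + new_tf)
            accepted_theta = np.vstack([accepted_theta] + new_theta)
        log.cycles.append(
            CycleRecord(
                cycle=cycle,
                n_candidates=len(batch),
                n_accepted=len(new_articles),
                corpus_size_after=len(accepted),
                refit=refit,
            )
        )
    return accepted, log, results


def threshold_sweep(
    sims_per_candidate: list[np.ndarray],
    thresholds: Sequence[float],
    min_matches: int = 5,
) -> list[dict]:
    """Acceptance count at each threshold, from precomputed similarity rows.

    Utility for the exploratory choice of the cut-off: given each candidate's
    similarities to the accepted corpus, reports how many candidates would be
    accepted at each threshold.
    """
    rows = []
    for t in thresholds:
        n_acc = sum(
            1 for sims in sims_per_candidate if int((sims >= t).sum()) >= min_matches
        )
        rows.append({"threshold": float(t), "n_accepted": n_acc})
    return rows
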