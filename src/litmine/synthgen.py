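"""Ground-truth synthetic data for every stage of the pipeline.

Emulates, with known truth, the inputs the toolkit consumes: topic-model
corpora drawn from the LDA generative process itself (so parameter recovery
can be scored against the true topic-word distributions), labelled candidate
streams mixing in-domain documents (drawn from the seed corpus's truth) with
off-domain documents over a shifted vocabulary block (for scoring the
expansion filter), screening decision tables, and rater-label tables with a
controlled noise rate (for scoring the consensus statistics).

Synthetic words are opaque strings ("w0017"), not English, so the stopword
logic of preprocessing is exercised via separately injected stopword tokens
rather than by linguistic content. What this generator deliberately does not
emulate: real abstract prose, MeSH structure, or the length and vocabulary
scale of real PubMed records.

All generators are pure functions of their spec + seed: the same seed yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Article
from .consensus import RaterTable
from .screening import REASON_CODES, ScreeningRecord

__all__ = [
    "GeneratorSpec",
    "gen_corpus",
    "gen_candidate_stream",
    "gen_screening_records",
    "gen_rater_table",
]


@dataclass
class GeneratorSpec:
    """Conditions of the synthetic study.

    topic_separation is the concentration of the topic-word Dirichlet
    (lower = more separable topics); ``disjoint_topics`` instead gives each
    topic an exclusive vocabulary block. alpha_true concentrates each
    document on few topics. Document lengths are Poisson(doc_length_mean)
    (min 1). offdomain_fraction and offdomain_vocab_size control the
    candidate stream; rater_noise the label simulation.
    """

    K_true: int = 5
    vocab_size: int = 100
    n_docs: int = 100
    doc_length_mean: float = 60.0
    alpha_true: float = 0.1
    topic_separation: float = 0.05
    disjoint_topics: bool = False
    offdomain_fraction: float = 0.3
    offdomain_vocab_size: int = 50
    rater_noise: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.K_true, self.vocab_size, self.n_docs) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.offdomain_fraction <= 1:
            raise ValueError("offdomain_fraction must be in [0, 1]")
        if not 0 <= self.rater_noise <= 1:
            raise ValueError("rater_noise must be in [0, 1]")
        if self.disjoint_topics and self.vocab_size < self.K_true:
            raise ValueError("vocab_size < K_true with disjoint topic blocks")


@dataclass
class CorpusTruth:
    """The generative ground truth behind a synthetic corpus."""

    phi: np.ndarray  # K_true x V
    theta: np.ndarray  # n_docs x K_true
    z: list[np.ndarray]  # per-document token topic assignments


def _word(w: int) -> str:
    """Opaque alphabetic token for word index w ("wbjh" for 0197).

    Digits are mapped to letters so tokens survive alphabetic-only
    tokenisation when synthetic records round-trip through the file formats.
    """
    digits = f"{w:04d}"
    return "w" + "".join(chr(ord("a") + int(c)) for c in digits)


def word_index(token: str) -> int:
    """Inverse of the synthetic word rendering."""
    return int("".join(str(ord(c) - ord("a")) for c in token[1:]))


def _sample_phi(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    K, V = spec.K_true, spec.vocab_size
    if spec.disjoint_topics:
        # exclusive contiguous vocabulary blocks per topic
        phi = np.zeros((K, V))
        bounds = np.linspace(0, V, K + 1).astype(int)
        for k in range(K):
            lo, hi = bounds[k], bounds[k + 1]
            block = rng.dirichlet(np.full(hi - lo, 1.0))
            phi[k, lo:hi] = block
        return phi
    return rng.dirichlet(np.full(V, spec.topic_separation), size=K)


def gen_corpus(
    spec: GeneratorSpec,
    stopword_tokens: Sequence[str] = (),
    prefix: str = "S",
) -> tuple[list[Article], CorpusTruth]:
    """Draw a corpus from the LDA generative process; return articles + truth.

    Each document's tokens are rendered as opaque word strings joined into
    the abstract field (titles carry a fixed pseudo-title). If
    ``stopword_tokens`` are given they are interleaved into the text (one per
    document, round-robin) to exercise stopword filtering; they are not part
    of the generative truth.
    """
    rng = np.random.default_rng(spec.seed)
    phi = _sample_phi(spec, rng)
    theta = rng.dirichlet(np.full(spec.K_true, spec.alpha_true), size=spec.n_docs)
    articles, zs = [], []
    for d in range(spec.n_docs):
        n = max(1, int(rng.poisson(spec.doc_length_mean)))
        z = rng.choice(spec.K_true, size=n, p=theta[d])
        words = [int(rng.choice(spec.vocab_size, p=phi[k])) for k in z]
        text_tokens = [_word(w) for w in words]
        if stopword_tokens:
            text_tokens.insert(0, stopword_tokens[d % len(stopword_tokens)])
        articles.append(
            Article(
                id=f"{prefix}{d:05d}",
                title=f"synthetic record {d}",
                abstract=" ".join(text_tokens),
                tokens=[_word(w) for w in words],
            )
        )
        zs.append(z)
    return articles, CorpusTruth(phi=phi, theta=theta, z=zs)


def gen_candidate_stream(
    spec: GeneratorSpec,
    truth: CorpusTruth,
    n_candidates: int = 200,
    prefix: str = "C",
) -> tuple[list[Article], list[str]]:
    """Labelled candidate stream: in-domain vs off-domain documents.

    In-domain candidates are drawn from the seed corpus's generative truth
    (same phi, fresh theta). Off-domain candidates are uniform draws over a
    disjoint vocabulary block appended after the seed vocabulary, so their
    word vectors share no support with any seed document. Returns the
    articles and a parallel label list ('in_domain' | 'off_domain').
    """
    rng = np.random.default_rng(spec.seed + 1)
    K, V = truth.phi.shape
    articles, labels = [], []
    for i in range(n_candidates):
        off = bool(rng.random() < spec.offdomain_fraction)
        n = max(1, int(rng.poisson(spec.doc_length_mean)))
        if off:
            words = V + rng.integers(0, spec.offdomain_vocab_size, size=n)
        else:
            th = rng.dirichlet(np.full(K, spec.alpha_true))
            z = rng.choice(K, size=n, p=th)
            words = np.array([int(rng.choice(V, p=truth.phi[k])) for k in z])
        tokens = [_word(int(w)) for w in words]
        articles.append(
            Article(
                id=f"{prefix}{i:05d}",
                title=f"candidate record {i}",
                abstract=" ".join(tokens),
                tokens=tokens,
            )
        )
        labels.append("off_domain" if off else "in_domain")
    return articles, labels


def gen_screening_records(
    n_scraped: int,
    n_included: int,
    reason_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ScreeningRecord]:
    """Screening table with the given inclusion count and random overlapping reasons."""
    rng = np.random.default_rng(seed)
    probs = reason_probs or {c: 0.3 for c in REASON_CODES}
    records = []
    for i in range(n_scraped):
        if i < n_included:
            records.append(ScreeningRecord(f"A{i:06d}", "included"))
        else:
            reasons = tuple(c for c in probs if rng.random() < probs[c])
            if not reasons:
                reasons = (str(rng.choice(list(probs))),)
            records.append(ScreeningRecord(f"A{i:06d}", "excluded", reasons))
    return records


def gen_rater_table(
    T: int,
    R: int,
    noise_rate: float,
    label_alphabet: Sequence[str],
    seed: int = 0,
) -> tuple[RaterTable, list[str]]:
    """Rater table under a "true label + uniform noise" model.

    Each topic t has a true label; each rater reports it with probability
    1 - noise_rate, otherwise a label drawn uniformly from the other
    alphabet entries. Returns the table and the true labels.
    """
    if R < 2:
        raise ValueError("need >= 2 raters")
    if not 0 <= noise_rate <= 1:
        raise ValueError("noise_rate must be in [0, 1]")
    if len(label_alphabet) < 2 and noise_rate > 0:
        raise ValueError("label alphabet must have >= 2 entries when noise > 0")
    rng = np.random.default_rng(seed)
    alphabet = list(label_alphabet)
    true = [alphabet[int(rng.integers(len(alphabet)))] for _ in range(T)]
    cells = np.empty((R, T), dtype=object)
    for t in range(T):
        others = [l for l in alphabet if l != true[t]]
        for r in range(R):
            if rng.random() < noise_rate and others:
                cells[r, t] = others[int(rng.integers(len(others)))]
            else:
                cells[r, t] = true[t]
    df = pd.DataFrame(cells, columns=[f"topic_{t+1}" for t in range(T)])
    return RaterTable(df), true
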