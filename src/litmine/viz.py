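"""Topic-map quantities: relevance-ranked terms, prevalence, inter-topic distances.

Computes everything one reads off an intertopic-distance visualisation of a
fitted topic model without rendering anything: per-topic top-N terms ranked by
lambda-relevance, per-topic prevalence (the "circle size": the topic's share
of corpus token mass), pairwise Jensen-Shannon divergences between topic-word
distributions (the inter-circle distance), a 2D principal-coordinates layout
of that distance matrix, and a quantitative sweep over candidate topic counts
(separation / evenness / overlap diagnostics standing in for the manual
judgement of which K "looks right").

Relevance of word w to topic k at interpolation weight lambda in [0, 1]:

    r(w, k | lambda) = lambda * log phi_kw + (1 - lambda) * log(phi_kw / p_w)

lambda = 1 ranks by within-topic probability, lambda = 0 by lift over the
corpus-wide term distribution p_w; the default 0.6 is the commonly
recommended compromise. Saliency is the companion corpus-level score
p_w * KL(p(topic | w) || prevalence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import BowCorpus
from .lda import LDA, LDAResults

__all__ = [
    "relevance",
    "saliency",
    "jensen_shannon",
    "intertopic_map",
    "topic_summaries",
    "sweep_topic_counts",
    "TopicMap",
    "TopicSummary",
]

SCHEMA_VERSION = 1


def relevance(phi_kw, p_w, lam: float = 0.6):
    """lambda-relevance score; inputs may be scalars or arrays in (0, 1]."""
    phi_kw = np.asarray(phi_kw, dtype=float)
    p_w = np.asarray(p_w, dtype=float)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if np.any(phi_kw <= 0) or np.any(p_w <= 0):
        raise ValueError("relevance requires strictly positive probabilities")
    return lam * np.log(phi_kw) + (1.0 - lam) * np.log(phi_kw / p_w)


def saliency(p_w, topic_given_word, prevalence):
    """Corpus-level term informativeness: p_w * KL(p(k|w) || prevalence).

    ``topic_given_word`` is the length-K posterior p(topic | word) for one
    word (or an array W x K); ``prevalence`` the length-K topic prevalence.
    """
    p_w = np.asarray(p_w, dtype=float)
    q = np.atleast_2d(np.asarray(topic_given_word, dtype=float))
    prev = np.asarray(prevalence, dtype=float)
    if np.any(q < 0) or np.any(prev <= 0):
        raise ValueError("invalid distributions")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q / prev), 0.0)
    kl = terms.sum(axis=1)
    out = p_w * kl
    return float(out) if np.isscalar(p_w) or out.shape == () else out


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with natural log; symmetric, in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def _pcoa_2d(dist: np.ndarray) -> np.ndarray:
    """Classical MDS (principal coordinates) of a distance matrix, 2 axes.

    Double-centres the squared distances, eigendecomposes, keeps the two
    leading non-negative eigenpairs; coordinates are centred at the origin.
    """
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    coords = np.zeros((n, 2))
    for axis, idx in enumerate(order[:2]):
        if evals[idx] > 1e-12:
            coords[:, axis] = evecs[:, idx] * np.sqrt(evals[idx])
    return coords - coords.mean(axis=0)


@dataclass
class TopicSummary:
    """One topic's ranked term table plus prevalence and map position."""

    topic_id: int
    prevalence: float
    # (word, within-topic frequency, corpus-wide frequency, relevance)
    top_terms: list[tuple[str, float, float, float]]
    xy: tuple[float, float]


@dataclass
class TopicMap:
    """Inter-topic distances and their 2D principal-coordinates layout."""

    distance_matrix: np.ndarray
    coords: np.ndarray
    lam: float
    prevalence: np.ndarray = field(default=None)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.distance_matrix, delimiter=",", fmt="%.10g")

    def plot(self, ax=None, labels: list[str] | None = None):
        """Draw the topic map: circles at the PCoA coordinates, area
        proportional to prevalence. Returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prev = (
            self.prevalence
            if self.prevalence is not None
            else np.full(len(self.coords), 1.0 / len(self.coords))
        )
        sizes = 2000 * np.asarray(prev)
        ax.scatter(self.coords[:, 0], self.coords[:, 1], s=sizes, alpha=0.5)
        for k, (x, y) in enumerate(self.coords):
            ax.annotate(labels[k] if labels else str(k), (x, y),
                        ha="center", va="center")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_aspect("equal")
        return ax


def intertopic_map(results: LDAResults, lam: float = 0.6) -> TopicMap:
    """Pairwise JSD between topic-word rows and their 2D PCoA layout."""
    K = results.K
    if K < 2:
        raise ValueError("map undefined for one topic")
    dist = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            dist[i, j] = dist[j, i] = jensen_shannon(results.phi[i], results.phi[j])
    return TopicMap(
        distance_matrix=dist,
        coords=_pcoa_2d(dist),
        lam=lam,
        prevalence=results.prevalence(),
    )


def topic_summaries(
    results: LDAResults,
    n_terms: int = 30,
    lam: float = 0.6,
) -> list[TopicSummary]:
    """Per-topic top-``n_terms`` relevance-ranked terms with both frequencies.

    "Within-topic frequency" is the topic's expected count of the term
    (prevalence_k * N * phi_kw); "corpus-wide frequency" the model-implied
    overall expected count (N * p_w) — the red and blue bars of the usual
    term histogram.
    """
    vocab = results.model.vocabulary
    n_terms = min(n_terms, results.model.corpus.vocab_size)
    prev = results.prevalence()
    p_w = results.term_distribution()
    n_tokens = results.model.corpus.n_tokens
    tmap = intertopic_map(results, lam) if results.K >= 2 else None
    summaries = []
    for k in range(results.K):
        scores = relevance(results.phi[k], p_w, lam)
        top = np.argsort(-scores, kind="stable")[:n_terms]
        terms = [
            (
                vocab[w] if vocab else f"w{w}",
                float(prev[k] * n_tokens * results.phi[k, w]),
                float(n_tokens * p_w[w]),
                float(scores[w]),
            )
            for w in top
        ]
        xy = tuple(tmap.coords[k]) if tmap is not None else (0.0, 0.0)
        summaries.append(
            TopicSummary(topic_id=k, prevalence=float(prev[k]), top_terms=terms, xy=xy)
        )
    return summaries


def export_json(
    results: LDAResults,
    path: str | Path,
    n_terms: int = 30,
    lam: float = 0.6,
) -> dict:
    """Schema-versioned JSON export of coordinates, prevalence and term tables."""
    summaries = topic_summaries(results, n_terms=n_terms, lam=lam)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "K": results.K,
        "lambda": lam,
        "topics": [asdict(s) for s in summaries],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def sweep_topic_counts(
    corpus: BowCorpus,
    K_list: list[int],
    seed: int = 0,
    n_iter: int = 300,
    overlap_threshold: float = 0.2,
    alpha: float | None = None,
    beta: float = 0.01,
) -> list[dict]:
    """Fit the model at each K and report separation / evenness / overlap.

    For each K: ``separation`` = mean pairwise JSD between topics,
    ``evenness`` = prevalence entropy normalised by log K, ``overlap`` =
    number of topic pairs with JSD below ``overlap_threshold``. Separation
    and overlap are undefined (None) at K = 1. Deterministic given ``seed``.
    """
    if not K_list:
        raise ValueError("K_list must be non-empty")
    rows = []
    for K in K_list:
        res = LDA(corpus, K=K, alpha=alpha, beta=beta).fit(n_iter=n_iter, seed=seed)
        prev = res.prevalence()
        if K >= 2:
            tmap = intertopic_map(res)
            iu = np.triu_indices(K, k=1)
            pair_d = tmap.distance_matrix[iu]
            separation = float(pair_d.mean())
            overlap = int((pair_d < overlap_threshold).sum())
            evenness = float(-(prev * np.log(prev)).sum() / np.log(K))
        else:
            separation, overlap, evenness = None, None, 1.0
        rows.append(
            {
                "K": K,
                "separation": separation,
                "evenness": evenness,
                "overlap": overlap,
                "perplexity": res.perplexity(corpus),
            }
        )
    return rows
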