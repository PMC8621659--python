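"""Latent Dirichlet allocation fitted by collapsed Gibbs sampling.

The model: each of K topics is a distribution phi_k over the V vocabulary
words (symmetric Dirichlet(beta) prior); each document d mixes topics with
weights theta_d (symmetric Dirichlet(alpha) prior); every token is generated
by drawing a topic z from theta_d and a word from phi_z. Collapsed Gibbs
sampling integrates phi and theta out analytically and resamples each token's
topic assignment from its full conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

where the count tables n_dk (doc-topic), n_kw (topic-word) and n_k (topic
totals) exclude token i. Point estimates are posterior means given the final
assignment state:

    phi_kw   = (n_kw + beta) / (n_k + V*beta)
    theta_dk = (n_dk + alpha) / (n_d + K*alpha)

Organised statsmodels-style: :class:`LDA` is the model object built from a
:class:`~litmine.corpus.BowCorpus`; ``fit()`` returns :class:`LDAResults`
carrying the estimates, diagnostics, ``fold_in`` inference for new documents,
``perplexity`` and a ``summary()`` table.

Reproducibility: a single integer seed drives the token-level initial
assignments and all sweeps; two runs with the same seed are bitwise
identical. Topics are renumbered in decreasing order of marginal prevalence
(ties broken by lowest dominant word ID) so numbering is stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import gammaln

from .corpus import BowCorpus

__all__ = ["LDA", "LDAResults", "FitReport"]


@njit(cache=False)
def _gibbs_sweeps(
    doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, beta, n_sweeps, seed
):  # pragma: no cover - exercised via LDA.fit
    np.random.seed(seed)
    K = n_kw.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    p = np.empty(K)
    for _ in range(n_sweeps):
        for i in range(doc_ids.shape[0]):
            d = doc_ids[i]
            w = word_ids[i]
            k_old = z[i]
            n_dk[d, k_old] -= 1
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            total = 0.0
            for k in range(K):
                total += (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + vbeta)
                p[k] = total
            u = np.random.random() * total
            k_new = 0
            while p[k_new] < u:
                k_new += 1
            z[i] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1


@njit(cache=False)
def _init_assignments(doc_ids, word_ids, K, seed):  # pragma: no cover
    np.random.seed(seed)
    N = doc_ids.shape[0]
    z = np.empty(N, dtype=np.int64)
    for i in range(N):
        z[i] = np.random.randint(0, K)
    return z


@njit(cache=False)
def _fold_in_sweeps(words, m_k, phi, alpha, n_sweeps, burn_in, seed):  # pragma: no cover
    """Gibbs over one document with phi fixed; returns summed post-burn-in m_k."""
    np.random.seed(seed)
    K = phi.shape[0]
    n = words.shape[0]
    z = np.empty(n, dtype=np.int64)
    for i in range(n):
        z[i] = np.random.randint(0, K)
        m_k[z[i]] += 1
    acc = np.zeros(K)
    p = np.empty(K)
    for sweep in range(n_sweeps):
        for i in range(n):
            k_old = z[i]
            m_k[k_old] -= 1
            total = 0.0
            for k in range(K):
                total += phi[k, words[i]] * (m_k[k] + alpha)
                p[k] = total
            u = np.random.random() * total
            k_new = 0
            while p[k_new] < u:
                k_new += 1
            z[i] = k_new
            m_k[k_new] += 1
        if sweep >= burn_in:
            for k in range(K):
                acc[k] += m_k[k]
    return acc


def _flatten(corpus: BowCorpus) -> tuple[np.ndarray, np.ndarray]:
    """Expand (word, count) vectors into per-token doc/word index arrays."""
    doc_ids, word_ids = [], []
    for d, doc in enumerate(corpus.docs):
        for w, c in doc:
            doc_ids.extend([d] * c)
            word_ids.extend([w] * c)
    return np.asarray(doc_ids, dtype=np.int64), np.asarray(word_ids, dtype=np.int64)


def collapsed_log_joint(
    n_dk: np.ndarray, n_kw: np.ndarray, alpha: float, beta: float
) -> float:
    """log p(w, z) with phi and theta integrated out (up to const in w order).

    Product of Dirichlet-multinomial normalisers over documents and topics.
    """
    D, K = n_dk.shape
    V = n_kw.shape[1]
    n_d = n_dk.sum(axis=1)
    n_k = n_kw.sum(axis=1)
    ll = D * (gammaln(K * alpha) - K * gammaln(alpha))
    ll += float(gammaln(n_dk + alpha).sum() - gammaln(n_d + K * alpha).sum())
    ll += K * (gammaln(V * beta) - V * gammaln(beta))
    ll += float(gammaln(n_kw + beta).sum() - gammaln(n_k + V * beta).sum())
    return ll


@dataclass
class FitReport:
    """Convergence diagnostics for one Gibbs run."""

    log_likelihood_trace: np.ndarray
    perplexity: float
    converged: bool
    n_iter: int
    burn_in: int


class LDA:
    """LDA model over a bag-of-words corpus.

    Parameters
    ----------
    corpus : BowCorpus
        Training documents as sparse count vectors.
    K : int
        Number of topics, fixed a priori.
    alpha : float, optional
        Symmetric document-topic Dirichlet concentration. Default 50/K, a
        standard topic-modelling heuristic.
    beta : float, optional
        Symmetric topic-word Dirichlet concentration. Default 0.01.
    vocabulary : list of str, optional
        ID-ordered word strings, used only for reporting.
    """

    def __init__(
        self,
        corpus: BowCorpus,
        K: int,
        alpha: float | None = None,
        beta: float = 0.01,
        vocabulary: list[str] | None = None,
    ):
        if corpus.n_docs == 0:
            raise ValueError("empty corpus")
        if K < 1:
            raise ValueError(f"K must be >= 1, got {K}")
        if alpha is not None and alpha <= 0:
            raise ValueError("alpha must be > 0")
        if beta <= 0:
            raise ValueError("beta must be > 0")
        self.corpus = corpus
        self.K = int(K)
        self.alpha = float(alpha) if alpha is not None else 50.0 / K
        self.beta = float(beta)
        self.vocabulary = vocabulary
        self._doc_ids, self._word_ids = _flatten(corpus)
        if K > self._word_ids.shape[0]:
            warnings.warn(
                f"K={K} exceeds the total token count {self._word_ids.shape[0]}",
                stacklevel=2,
            )

    def fit(
        self,
        n_iter: int = 1000,
        seed: int = 0,
        burn_in_fraction: float = 0.5,
        trace_every: int = 10,
    ) -> "LDAResults":
        """Run collapsed Gibbs sampling and return posterior-mean estimates.

        Single chain; the log joint is traced every ``trace_every`` sweeps and
        convergence is declared when the post-burn-in trace has no practically
        relevant upward trend (relative slope < 1e-4 per sweep).
        """
        D, V, K = self.corpus.n_docs, self.corpus.vocab_size, self.K
        doc_ids, word_ids = self._doc_ids, self._word_ids
        z = _init_assignments(doc_ids, word_ids, K, seed)
        n_dk = np.zeros((D, K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        np.add.at(n_dk, (doc_ids, z), 1)
        np.add.at(n_kw, (z, word_ids), 1)
        np.add.at(n_k, z, 1)

        trace = []
        burn_in = int(round(burn_in_fraction * n_iter))
        done = 0
        sweep_seed = (seed + 1) % 2**31
        while done < n_iter:
            step = min(trace_every, n_iter - done)
            _gibbs_sweeps(
                doc_ids, word_ids, z, n_dk, n_kw, n_k,
                self.alpha, self.beta, step, (sweep_seed + done) % 2**31,
            )
            done += step
            trace.append(collapsed_log_joint(n_dk, n_kw, self.alpha, self.beta))
        trace_arr = np.asarray(trace)
        converged = True
        if len(trace_arr) >= 4:
            tail = trace_arr[len(trace_arr) // 2 :]
            slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
            converged = bool(slope < 1e-4 * abs(tail[-1]) / max(trace_every, 1) + 1e-9)

        results = LDAResults(self, z, n_dk, n_kw, n_k, n_iter=n_iter, seed=seed)
        report = FitReport(
            log_likelihood_trace=trace_arr,
            perplexity=results.perplexity(self.corpus),
            converged=converged,
            n_iter=n_iter,
            burn_in=burn_in,
        )
        results.report = report
        return results


class LDAResults:
    """Fitted LDA state: estimates, count tables, diagnostics and inference."""

    def __init__(
        self,
        model: LDA,
        z: np.ndarray,
        n_dk: np.ndarray,
        n_kw: np.ndarray,
        n_k: np.ndarray,
        n_iter: int,
        seed: int,
    ):
        self.model = model
        self.K = model.K
        self.alpha = model.alpha
        self.beta = model.beta
        self.n_iter = n_iter
        self.seed = seed
        self.z = z
        self.report: FitReport | None = None

        V = model.corpus.vocab_size
        n_d = n_dk.sum(axis=1, keepdims=True)
        phi = (n_kw + self.beta) / (n_k[:, None] + V * self.beta)
        theta = (n_dk + self.alpha) / (n_d + self.K * self.alpha)

        # stable topic numbering: decreasing prevalence, ties by dominant word ID
        prevalence = theta.sum(axis=0)
        dominant = phi.argmax(axis=1)
        order = sorted(range(self.K), key=lambda k: (-prevalence[k], dominant[k]))
        self._order = np.asarray(order)
        self.phi = np.ascontiguousarray(phi[self._order])
        self.theta = np.ascontiguousarray(theta[:, self._order])
        self.n_dk = np.ascontiguousarray(n_dk[:, self._order])
        self.n_kw = np.ascontiguousarray(n_kw[self._order])
        self.n_k = np.ascontiguousarray(n_k[self._order])

    # ------------------------------------------------------------------ #

    def check_counts(self) -> None:
        """Assert internal consistency of the count tables (debug aid)."""
        lengths = self.model.corpus.doc_lengths()
        assert (self.n_dk.sum(axis=1) == lengths).all(), "doc-topic counts != doc lengths"
        assert (self.n_kw.sum(axis=1) == self.n_k).all(), "topic-word counts != topic totals"
        assert self.n_dk.sum() == self.n_k.sum() == lengths.sum()

    def prevalence(self) -> np.ndarray:
        """Token-mass share of each topic: sum_d n_d * theta_dk / sum_d n_d."""
        n_d = self.model.corpus.doc_lengths().astype(float)
        mass = (n_d[:, None] * self.theta).sum(axis=0)
        return mass / n_d.sum()

    def term_distribution(self) -> np.ndarray:
        """Corpus-wide term distribution implied by the model: sum_k prev_k phi_kw."""
        return self.prevalence() @ self.phi

    def fold_in(
        self,
        bow: list[tuple[int, int]],
        n_iter: int = 200,
        seed: int = 0,
        burn_in_fraction: float = 0.5,
    ) -> tuple[np.ndarray, bool]:
        """Infer a new document's topic distribution with phi held fixed.

        Returns ``(theta_new, was_empty)``. The topic distribution is the
        posterior mean averaged over post-burn-in sweeps. An empty document
        (after out-of-vocabulary drop) yields the uniform distribution with
        ``was_empty=True``.
        """
        words = np.asarray(
            [w for w, c in bow if w < self.model.corpus.vocab_size for _ in range(c)],
            dtype=np.int64,
        )
        if words.size == 0:
            return np.full(self.K, 1.0 / self.K), True
        burn_in = int(round(burn_in_fraction * n_iter))
        m_k = np.zeros(self.K, dtype=np.int64)
        acc = _fold_in_sweeps(
            words, m_k, self.phi, self.alpha, n_iter, burn_in, seed % 2**31
        )
        n_kept = n_iter - burn_in
        mean_counts = acc / n_kept
        theta = (mean_counts + self.alpha) / (words.size + self.K * self.alpha)
        return theta / theta.sum(), False

    def perplexity(self, corpus: BowCorpus, theta: np.ndarray | None = None) -> float:
        """exp(-mean per-token log likelihood) under the mixture sum_k theta phi.

        With ``theta=None`` on the training corpus, uses the training theta;
        for other corpora each document is folded in first.
        """
        if corpus.n_tokens == 0:
            raise ValueError("perplexity undefined for an empty corpus")
        if theta is None:
            if corpus is self.model.corpus:
                theta = self.theta
            else:
                theta = np.vstack(
                    [self.fold_in(doc, seed=i)[0] for i, doc in enumerate(corpus.docs)]
                )
        total_ll = 0.0
        for d, doc in enumerate(corpus.docs):
            for w, c in doc:
                pw = float(theta[d] @ self.phi[:, w])
                if pw <= 0:
                    raise FloatingPointError(
                        f"zero probability for word {w} in doc {d}"
                    )
                total_ll += c * np.log(pw)
        return float(np.exp(-total_ll / corpus.n_tokens))

    def summary(self, n_terms: int = 10) -> str:
        """Plain-text per-topic summary: prevalence and top terms by phi."""
        vocab = self.model.vocabulary
        prev = self.prevalence()
        lines = [
            "LDA fit: K=%d, alpha=%.4g, beta=%.4g, n_iter=%d, seed=%d"
            % (self.K, self.alpha, self.beta, self.n_iter, self.seed),
            "%-6s %-10s %s" % ("topic", "prevalence", "top terms"),
        ]
        for k in range(self.K):
            top = np.argsort(self.phi[k])[::-1][:n_terms]
            words = [vocab[w] if vocab else f"w{w}" for w in top]
            lines.append("%-6d %-10.4f %s" % (k, prev[k], " ".join(words)))
        return "\n".join(lines)

    # ----------------------------- serialisation ---------------------- #

    def save(self, path: str | Path) -> None:
        """Serialise the fitted state to a single JSON bundle."""
        corpus_hash = hashlib.sha256(
            json.dumps(self.model.corpus.docs).encode()
        ).hexdigest()
        payload = {
            "K": self.K,
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "vocab_size": self.model.corpus.vocab_size,
            "corpus_hash": corpus_hash,
            "vocabulary": self.model.vocabulary,
            "phi": self.phi.tolist(),
            "theta": self.theta.tolist(),
            "n_kw": self.n_kw.tolist(),
            "n_dk": self.n_dk.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path, corpus: BowCorpus) -> "LDAResults":
        payload = json.loads(Path(path).read_text())
        model = LDA(
            corpus,
            K=payload["K"],
            alpha=payload["alpha"],
            beta=payload["beta"],
            vocabulary=payload.get("vocabulary"),
        )
        n_dk = np.asarray(payload["n_dk"], dtype=np.int64)
        n_kw = np.asarray(payload["n_kw"], dtype=np.int64)
        res = cls(
            model,
            z=np.empty(0, dtype=np.int64),
            n_dk=n_dk,
            n_kw=n_kw,
            n_k=n_kw.sum(axis=1),
            n_iter=payload["n_iter"],
            seed=payload["seed"],
        )
        return res
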