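"""Independent reference computations used by the tests.

Everything here is written from first principles (lgamma loops, explicit
enumeration, plain cosine arithmetic) and deliberately shares no code with
the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def collapsed_log_prob(
    assignment: tuple[int, ...],
    doc_of_token: list[int],
    word_of_token: list[int],
    D: int,
    V: int,
    K: int,
    alpha: float,
    beta: float,
) -> float:
    """log p(w, z) for one full assignment vector, Dirichlet-multinomial form."""
    n_dk = [[0] * K for _ in range(D)]
    n_kw = [[0] * V for _ in range(K)]
    for z, d, w in zip(assignment, doc_of_token, word_of_token):
        n_dk[d][z] += 1
        n_kw[z][w] += 1
    lp = 0.0
    for d in range(D):
        n_d = sum(n_dk[d])
        lp += math.lgamma(K * alpha) - math.lgamma(n_d + K * alpha)
        for k in range(K):
            lp += math.lgamma(n_dk[d][k] + alpha) - math.lgamma(alpha)
    for k in range(K):
        n_k = sum(n_kw[k])
        lp += math.lgamma(V * beta) - math.lgamma(n_k + V * beta)
        for w in range(V):
            lp += math.lgamma(n_kw[k][w] + beta) - math.lgamma(beta)
    return lp


def enumerate_posterior(
    doc_of_token: list[int],
    word_of_token: list[int],
    D: int,
    V: int,
    K: int,
    alpha: float,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior by enumerating all K^N assignment vectors.

    Returns (marginals[N, K], coassign[N, N]) where coassign[i, j] =
    p(z_i == z_j); the co-assignment matrix is invariant to topic
    relabelling and is the informative quantity under symmetric priors.
    """
    N = len(doc_of_token)
    logps = []
    assignments = list(itertools.product(range(K), repeat=N))
    for a in assignments:
        logps.append(
            collapsed_log_prob(a, doc_of_token, word_of_token, D, V, K, alpha, beta)
        )
    logps = np.asarray(logps)
    p = np.exp(logps - logps.max())
    p /= p.sum()
    marginals = np.zeros((N, K))
    coassign = np.zeros((N, N))
    for prob, a in zip(p, assignments):
        for i in range(N):
            marginals[i, a[i]] += prob
            for j in range(N):
                if a[i] == a[j]:
                    coassign[i, j] += prob
    return marginals, coassign


def batch_means_se(indicator: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of a chain mean via batch means."""
    n = len(indicator) // n_batches * n_batches
    batches = indicator[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / math.sqrt(n_batches))


def cosine(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def unigram_perplexity(counts: np.ndarray, beta: float) -> float:
    """exp cross-entropy of the beta-smoothed empirical unigram distribution."""
    counts = np.asarray(counts, float)
    V = len(counts)
    N = counts.sum()
    p = (counts + beta) / (N + V * beta)
    ce = -(counts * np.log(p)).sum() / N
    return float(math.exp(ce))


def gibbs_coassignment(
    doc_of_token,
    word_of_token,
    D: int,
    V: int,
    K: int,
    alpha: float,
    beta: float,
    n_sweeps: int,
    burn_in: int,
    seed: int,
):
    """Post-burn-in co-assignment indicators from the package's Gibbs kernel.

    Drives litmine's sampler one sweep at a time so per-sweep states can be
    recorded; returns indicator series of shape (kept_sweeps, N, N).
    """
    from litmine.lda import _gibbs_sweeps, _init_assignments

    doc_ids = np.asarray(doc_of_token, dtype=np.int64)
    word_ids = np.asarray(word_of_token, dtype=np.int64)
    N = len(doc_ids)
    z = _init_assignments(doc_ids, word_ids, K, seed)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    np.add.at(n_dk, (doc_ids, z), 1)
    np.add.at(n_kw, (z, word_ids), 1)
    np.add.at(n_k, z, 1)
    kept = []
    for sweep in range(n_sweeps):
        _gibbs_sweeps(
            doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, beta, 1,
            (seed + 1 + sweep) % 2**31,
        )
        if sweep >= burn_in:
            kept.append(np.equal.outer(z, z).astype(float))
    return np.asarray(kept)
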