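"""Independent oracles used by the tests.

Each function recomputes a quantity by brute force or a closed form, never
through the code path it is meant to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_la(x: str, y: str, params) -> float:
    """LA kernel by exhaustive enumeration of all gapped local alignments.

    An alignment is a pair of equal-length increasing index tuples; its
    score is the sum of substitution scores minus affine penalties
    d + e*(g-1) for every internal gap of length g >= 1 in either sequence.
    The empty alignment contributes 1.
    """

    def gap_pen(g: int) -> float:
        return 0.0 if g == 0 else params.gap_open + params.gap_extend * (g - 1)

    total = 1.0
    for k in range(1, min(len(x), len(y)) + 1):
        for ii in itertools.combinations(range(len(x)), k):
            for jj in itertools.combinations(range(len(y)), k):
                s = sum(params.score(x[i], y[j]) for i, j in zip(ii, jj))
                s -= sum(
                    gap_pen(ii[t + 1] - ii[t] - 1) + gap_pen(jj[t + 1] - jj[t] - 1)
                    for t in range(k - 1)
                )
                total += math.exp(params.beta * s)
    return total


def best_local_alignment_score(x: str, y: str, params) -> float:
    """Smith-Waterman optimum under the same affine-gap scoring (>= 0)."""

    def gap_pen(g: int) -> float:
        return 0.0 if g == 0 else params.gap_open + params.gap_extend * (g - 1)

    best = 0.0
    for k in range(1, min(len(x), len(y)) + 1):
        for ii in itertools.combinations(range(len(x)), k):
            for jj in itertools.combinations(range(len(y)), k):
                s = sum(params.score(x[i], y[j]) for i, j in zip(ii, jj))
                s -= sum(
                    gap_pen(ii[t + 1] - ii[t] - 1) + gap_pen(jj[t + 1] - jj[t] - 1)
                    for t in range(k - 1)
                )
                best = max(best, s)
    return best


def explicit_pair_scores(W: np.ndarray, b: float, M, P, mi, pj) -> np.ndarray:
    """Scores via explicitly materialized Kronecker pair features."""
    Z = np.stack([np.kron(M[i], P[j]) for i, j in zip(mi, pj)])
    return Z @ np.asarray(W).ravel() + b


def explicit_objective_grad(W, b, M, P, mi, pj, y, lam):
    """Hinge objective and gradient from materialized pair features."""
    W = np.asarray(W, dtype=float)
    Z = np.stack([np.kron(M[i], P[j]) for i, j in zip(mi, pj)])
    scores = Z @ W.ravel() + b
    margins = y * scores
    f = np.maximum(0.0, 1.0 - margins).mean() + 0.5 * lam * np.sum(W * W)
    g = np.where(margins < 1.0, -y, 0.0)
    gw = (g[:, None] * Z).mean(axis=0) + lam * W.ravel()
    return f, gw.reshape(W.shape), g.mean()


def clipped_psd(K: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest PSD reconstruction: eigenvalues below eps are zeroed."""
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    w = np.where(w > eps, w, 0.0)
    return (U * w) @ U.T


def average_precision_by_hand(scores, labels) -> float:
    """Average precision with stable descending order, computed naively."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    # sorted() is stable, so ties keep input order
    precisions, tp = [], 0
    for rank, idx in enumerate(order, start=1):
        if labels[idx] == 1:
            tp += 1
            precisions.append(tp / rank)
    return sum(precisions) / len(precisions)
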