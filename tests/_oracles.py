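"""Independent oracles used to validate the production implementations.

These are deliberately written with different algorithms/iteration orders
than the code under test: a direct Newton-Raphson maximizer of the binomial
log-likelihood, an O(n^2) double-sum Moran's I, and a subset-from-above
hierarchical-partitioning average.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def newton_logistic(D: np.ndarray, k: np.ndarray, n: np.ndarray,
                    tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Newton-Raphson on the binomial log-likelihood, design matrix D."""
    D = np.asarray(D, float)
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    beta = np.zeros(D.shape[1])
    for _ in range(max_iter):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (k - n * p)
        H = -(D.T * (n * p * (1 - p))) @ D
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def brute_moran(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's I by explicit double loop."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return n / s0 * num / (z @ z)


def brute_hierpart_independent(gof: dict, predictors: list) -> dict:
    """Chevan-Sutherland independent contributions, iterated from above.

    For predictor j, average g(S) - g(S \\ {j}) over every subset S that
    contains j, weighting each hierarchy level equally.
    ``gof`` maps frozenset(subset) -> goodness of fit (null included).
    """
    k = len(predictors)
    out = {}
    for j in predictors:
        total = 0.0
        for size in range(1, k + 1):
            level = 0.0
            cnt = 0
            for S in itertools.combinations(predictors, size):
                if j not in S:
                    continue
                fs = frozenset(S)
                level += gof[fs] - gof[fs - {j}]
                cnt += 1
            assert cnt == comb(k - 1, size - 1)
            total += level / cnt
        out[j] = total / k
    return out
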