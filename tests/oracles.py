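"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately share no code with the package: naive dynamic
programming for alignment scores, closed-form least squares, dense grid
search for the progress-curve fit, and streaming (Welford) means.
"""

from __future__ import annotations

import math

import numpy as np

NEG_INF = float("-inf")


def gotoh_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Exhaustive affine-gap global alignment score.

    A gap of length L costs gap_open + (L-1)*gap_extend. ``score_fn``
    maps a residue pair to its substitution score.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def ols_line(x, y) -> tuple[float, float]:
    """Closed-form ordinary least squares slope and intercept."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    return slope, ybar - slope * xbar


def grid_search_progress(times, signal, v0_grid, kobs_grid) -> tuple[float, float]:
    """Dense grid search minimising RSS of the exponential product model."""
    t = np.asarray(times, float)
    y = np.asarray(signal, float)
    best = (math.inf, None, None)
    for v0 in v0_grid:
        for k in kobs_grid:
            model = (v0 / k) * (-np.expm1(-k * t)) if k > 0 else v0 * t
            rss = float(np.sum((model - y) ** 2))
            if rss < best[0]:
                best = (rss, v0, k)
    return best[1], best[2]


def welford_mean(values) -> float:
    """Streaming mean, numerically independent of sum()/len()."""
    mean = 0.0
    for i, v in enumerate(values, start=1):
        mean += (v - mean) / i
    return mean
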