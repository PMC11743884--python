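"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by explicit enumeration (python sets,
Floyd-Warshall loops, triangle counting, hand-rolled ranks) so the tests
can bind the vectorized implementations to first-principles definitions.
"""

from __future__ import annotations

import math

import numpy as np


def dice_pair_sets(a: set, b: set) -> float:
    denom = len(a) + len(b)
    if denom == 0:
        return float("nan")
    return 2.0 * len(a & b) / denom


def dice_third_order_sets(a: set, b: set, c: set) -> float:
    denom = len(a) + len(b) + len(c)
    if denom == 0:
        return float("nan")
    return 3.0 * len(a & b & c) / denom


def mpm_label_margin_rule(strengths: dict[str, float]) -> str:
    """Dominance via direct evaluation of |S_X - S_Y| > (S_X + S_Y)/2."""
    if all(v == 0 for v in strengths.values()):
        return "UNCLASSIFIED"
    for x, s_x in strengths.items():
        others = [s for k, s in strengths.items() if k != x]
        if all(s_x > s_y for s_y in others) and all(
            abs(s_x - s_y) > (s_x + s_y) / 2 for s_y in others
        ):
            return x
    return "OVERLAP"


def mpm_label_threefold_rule(strengths: dict[str, float]) -> str:
    """Dominance via the derived S_X > 3 S_Y form."""
    if all(v == 0 for v in strengths.values()):
        return "UNCLASSIFIED"
    for x, s_x in strengths.items():
        others = [s for k, s in strengths.items() if k != x]
        if all(s_x > 3 * s_y for s_y in others):
            return x
    return "OVERLAP"


def spearman_rho(x, y) -> float:
    """Average-rank Spearman via explicit rank construction."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook triple loop."""
    n = lengths.shape[0]
    d = lengths.copy().astype(float)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    lengths = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                lengths[i, j] = 1.0 / weights[i, j]
        lengths[i, i] = 0.0
    return lengths


def nodal_efficiency_oracle(weights: np.ndarray, node: int) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(_length_matrix(weights))
    total = 0.0
    for j in range(n):
        if j != node and np.isfinite(d[node, j]) and d[node, j] > 0:
            total += 1.0 / d[node, j]
    return total / (n - 1)


def global_efficiency_oracle(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    return sum(nodal_efficiency_oracle(weights, i) for i in range(n)) / n


def local_efficiency_oracle(weights: np.ndarray, node: int) -> float:
    nbrs = [j for j in range(weights.shape[0]) if weights[node, j] > 0]
    if len(nbrs) < 2:
        return 0.0
    sub = weights[np.ix_(nbrs, nbrs)]
    return global_efficiency_oracle(sub)


def clustering_oracle(weights: np.ndarray, node: int) -> float:
    """Geometric-mean triangle clustering via explicit triangle enumeration."""
    wmax = weights.max()
    if wmax == 0:
        return 0.0
    w = weights / wmax
    nbrs = [j for j in range(w.shape[0]) if w[node, j] > 0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    total = 0.0
    for j in nbrs:
        for h in nbrs:
            if j != h:
                total += (w[node, j] * w[node, h] * w[j, h]) ** (1.0 / 3.0)
    return total / (k * (k - 1))


def strength_oracle(weights: np.ndarray, node: int) -> float:
    return float(sum(weights[node, j] for j in range(weights.shape[0]) if j != node))
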