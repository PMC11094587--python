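"""Independent brute-force oracles, deliberately re-derived from first
principles and never calling into edmcast's own construction code paths."""

from __future__ import annotations

import math

import numpy as np


def crossing_out_library(T: int, E: int, t_star: int, radius_k: int | None = None):
    """Literal crossing-out of lag-matrix rows.

    Builds the symbolic T x E matrix whose cell (t, j) is the index t-j+1 of
    the difference value it would hold (None when outside 1..T-1), then
    removes rows per the exclusion conditions.  ``radius_k=None`` applies the
    look-ahead exclusion (d); an integer applies the temporal-radius variant
    instead.
    """
    L = T - 1  # number of defined first differences
    rows: dict[int, list[int | None]] = {}
    for t in range(1, T + 1):
        rows[t] = [(t - j + 1) if 1 <= (t - j + 1) <= L else None for j in range(1, E + 1)]

    kept = []
    for t in range(1, T + 1):
        if t == t_star:                       # (a)
            continue
        if any(c is None for c in rows[t]):   # (b)
            continue
        succ = t + 1
        if succ > T or any(c is None for c in rows[succ]):  # (c) x_{t+1} unknown
            continue
        if radius_k is None:
            if t_star + 1 <= t <= t_star + E:  # (d) contains Y_{t*+1}
                continue
        else:
            if abs(t - t_star) <= radius_k:
                continue
        kept.append(t)
    return kept


def euclid(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b, strict=True)))


def brute_force_simplex(y: np.ndarray, E: int, t_star: int, k: int | None = None,
                        radius_k: int | None = None) -> float:
    """Direct weighted-average prediction from sorted distances.

    ``y`` holds the differenced values Y_1..Y_L (0-based storage).  Recomputes
    the library, distances, ranks and Eq.-style weights from scratch.
    """
    T = len(y) + 1
    if k is None:
        k = E + 1
    lib = crossing_out_library(T, E, t_star, radius_k=radius_k)

    def vec(t):
        return [y[t - j - 1] for j in range(E)]  # (Y_t, Y_{t-1}, ..., Y_{t-E+1})

    focal = vec(t_star)
    ranked = sorted(lib, key=lambda t: (euclid(vec(t), focal), t))[:k]
    d = [euclid(vec(t), focal) for t in ranked]
    if d[0] > 0:
        w = [math.exp(-di / d[0]) for di in d]
    else:
        pos = [di for di in d if di > 0]
        w = [1.0 if di == 0 else math.exp(-di / min(pos)) for di in d]
    targets = [y[t] for t in ranked]  # Y_{t+1} is y[t] in 0-based storage
    return sum(wi * ti for wi, ti in zip(w, targets)) / sum(w)


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))
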