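"""Simplex projection: nearest-neighbour weighted one-step prediction.

Library members are ranked by Euclidean distance from the focal point; the
``E+1`` nearest form the simplex.  The prediction for the next time step is
the weighted average of where those neighbours went one step later,

    Y-hat_{t*+1} = sum_i w_i * Y_{psi_i + 1} / sum_j w_j,

with weights ``w_i = exp(-d_i / d_1)`` so the nearest neighbour always
carries weight ``exp(-1)`` when its distance is positive.

Everything here is deterministic: distance ties are broken by ascending time
index, and floating-point comparisons use exact equality on the computed
doubles (documented behaviour, no epsilon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .embedding import (
    LagMatrix,
    TimeSeries,
    build_lag_matrix,
    make_diff,
    undifference,
)
from .library import ExclusionPolicy, Library, Purpose, construct_library

__all__ = [
    "NeighbourSet",
    "PredictionResult",
    "ForecastResult",
    "euclidean_distance",
    "rank_neighbours",
    "simplex_weights",
    "predict_point",
    "forecast_next",
]

REMEDIES = ("none", "clamp_to_min", "log_transform")


@dataclass(frozen=True)
class NeighbourSet:
    """Ranked neighbours of one focal point.

    ``times[i]`` is ``psi_{i+1}``, the time index of the rank-``i+1``
    neighbour; ``distances`` are non-decreasing and ``weights`` lie in
    ``(0, 1]``, non-increasing with rank.
    """

    focal_t: int
    times: tuple[int, ...]
    distances: np.ndarray
    weights: np.ndarray


@dataclass(frozen=True)
class PredictionResult:
    focal_t: int
    y_hat: float
    neighbours: NeighbourSet
    n_hat: Optional[float] = None


@dataclass(frozen=True)
class ForecastResult:
    y_hat: float
    n_hat: float
    remedy: str
    E: int
    focal_t: int
    neighbours: NeighbourSet


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def rank_neighbours(
    lag: LagMatrix,
    library: Library,
    t_star: int,
    k: Optional[int] = None,
) -> NeighbourSet:
    """Return the ``k`` nearest library members to ``x_{t_star}``.

    ``k`` defaults to ``E + 1`` (the simplex).  Ties at any rank are broken
    by ascending time index.
    """
    if k is None:
        k = lag.E + 1
    if library.size < k:
        raise ValueError(
            f"library for t*={t_star} has only C={library.size} members; "
            f"k={k} neighbours requested"
        )
    focal = lag.row(t_star)
    members = np.array(library.member_times, dtype=int)
    diffs = lag.values[members - 1] - focal
    dists = np.sqrt(np.sum(diffs**2, axis=1))
    order = np.lexsort((members, dists))[:k]
    times = tuple(int(t) for t in members[order])
    distances = dists[order]
    return NeighbourSet(
        focal_t=t_star,
        times=times,
        distances=distances,
        weights=simplex_weights(distances),
    )


def simplex_weights(distances: np.ndarray) -> np.ndarray:
    """Exponential weights ``w_i = exp(-d_i / d_1)`` for ranked distances.

    Degenerate cases (the ratio is 0/0 when the nearest distance vanishes):
    zero-distance neighbours get weight 1; the remaining weights use the
    smallest positive distance as denominator; if every distance is zero the
    weights are all 1 (equal weighting).  This is the continuity-preserving
    limit and keeps the prediction a convex combination.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be ranked in ascending order")
    if d[0] > 0:
        return np.exp(-d / d[0])
    positive = d[d > 0]
    if positive.size == 0:
        return np.ones_like(d)
    w = np.ones_like(d)
    mask = d > 0
    w[mask] = np.exp(-d[mask] / positive.min())
    return w


def predict_point(
    lag: LagMatrix,
    t_star: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    k: Optional[int] = None,
    purpose: Purpose = "evaluation",
) -> PredictionResult:
    """One simplex prediction ``Y-hat_{t*+1}`` with full neighbour bookkeeping."""
    library = construct_library(lag, t_star, policy, purpose=purpose)
    return predict_from_library(lag, library, k=k)


def predict_from_library(
    lag: LagMatrix,
    library: Library,
    k: Optional[int] = None,
) -> PredictionResult:
    """As :func:`predict_point` but with a caller-supplied library (used for
    split-half evaluation, where the library is restricted to one half)."""
    nbrs = rank_neighbours(lag, library, library.t_star, k=k)
    targets = np.array([lag.target(t + 1) for t in nbrs.times])
    y_hat = float(np.sum(nbrs.weights * targets) / np.sum(nbrs.weights))
    return PredictionResult(focal_t=library.t_star, y_hat=y_hat, neighbours=nbrs)


def forecast_next(
    series: TimeSeries,
    E: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    remedy: str = "none",
    differencing: str = "first_difference",
    k: Optional[int] = None,
) -> ForecastResult:
    """Forecast one step beyond the data: ``Y-hat_{L+1}`` and ``N-hat_{T+1}``.

    Runs the simplex at the last focal time usable for forecasting (``T-1``
    when first-differencing, ``T`` otherwise) and undifferences.  Because the
    raw-scale forecast is not constrained to the observed range it can go
    negative even for a population series; remedies:

    ``clamp_to_min``
        Replace a negative ``N-hat`` with the smallest observed value.
    ``log_transform``
        Run the whole pipeline on ``log(N_t)`` and back-transform (requires a
        strictly positive series); the returned ``y_hat`` is then on the log
        scale.
    """
    if remedy not in REMEDIES:
        raise ValueError(f"unknown remedy {remedy!r}")
    if remedy == "log_transform":
        if np.any(series.values <= 0):
            raise ValueError("log_transform remedy requires strictly positive values")
        log_series = TimeSeries(np.log(series.values))
        inner = forecast_next(
            log_series, E, policy=policy, remedy="none", differencing=differencing, k=k
        )
        return ForecastResult(
            y_hat=inner.y_hat,
            n_hat=float(math.exp(inner.n_hat)),
            remedy="log_transform",
            E=E,
            focal_t=inner.focal_t,
            neighbours=inner.neighbours,
        )

    diff = make_diff(series, differencing)
    lag = build_lag_matrix(diff, E)
    t_star = lag.L  # last row whose state is fully known
    pred = predict_point(lag, t_star, policy=policy, k=k, purpose="forecast")
    if differencing == "first_difference":
        n_hat = undifference(pred.y_hat, series.at(series.T))
    else:
        n_hat = pred.y_hat
    if remedy == "clamp_to_min" and n_hat < 0:
        n_hat = float(series.values.min())
    return ForecastResult(
        y_hat=pred.y_hat,
        n_hat=float(n_hat),
        remedy=remedy,
        E=E,
        focal_t=t_star,
        neighbours=pred.neighbours,
    )
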