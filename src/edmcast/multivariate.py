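"""Multivariate delay embeddings.

State-space coordinates may be drawn from several co-observed series, each
with its own lag.  The first coordinate must be the prediction target at lag
0.  All focal-time and library index rules carry over from the univariate
case with the embedding dimension replaced by ``m + 1``, where ``m`` is the
maximum lag used by any coordinate — so the library size depends only on
``(T, m, t*)``, not on the number of variables.  A single variable with
consecutive lags ``0..E-1`` reproduces the univariate path bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .embedding import DiffSeries, LagMatrix, TimeSeries, make_diff
from .library import ExclusionPolicy, Library, construct_library

__all__ = ["CoordinateSpec", "MultivariateEmbedding", "build_multivariate_matrix", "multivariate_library"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoordinateSpec:
    """One state-space axis: a named variable at a non-negative lag."""

    variable: str
    lag: int

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be non-negative")


@dataclass(frozen=True)
class MultivariateEmbedding:
    """An ordered list of coordinates over a table of aligned series.

    The prediction target is always the first coordinate's variable one step
    ahead, so ``coords[0]`` must have lag 0.
    """

    coords: tuple[CoordinateSpec, ...]
    series_table: Mapping[str, TimeSeries]
    standardise: bool = False

    def __post_init__(self) -> None:
        coords = tuple(self.coords)
        object.__setattr__(self, "coords", coords)
        if not coords:
            raise ValueError("need at least one coordinate")
        if coords[0].lag != 0:
            raise ValueError("the first coordinate (the prediction target) must have lag 0")
        lengths = {name: ts.T for name, ts in self.series_table.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"all variables must have equal length, got {lengths}")
        for c in coords:
            if c.variable not in self.series_table:
                raise KeyError(f"unknown variable {c.variable!r}")

    @property
    def E(self) -> int:
        return len(self.coords)

    @property
    def m(self) -> int:
        """Maximum lag over all coordinates."""
        return max(c.lag for c in self.coords)

    @property
    def T(self) -> int:
        return next(iter(self.series_table.values())).T


def build_multivariate_matrix(
    emb: MultivariateEmbedding,
    differencing: str = "first_difference",
) -> LagMatrix:
    """Assemble the lag matrix: cell ``(t, j)`` holds variable ``j``'s
    (optionally differenced) value at ``t - lag_j``.

    Defined rows are ``{m+1 .. L}``; the matrix's exclusion ``span`` is set
    to ``m + 1`` so library construction applies the generalised rules.
    """
    diffs: dict[str, DiffSeries] = {
        name: make_diff(ts, differencing) for name, ts in emb.series_table.items()
    }
    L = next(iter(diffs.values())).L
    n_rows = emb.T
    E = emb.E
    values = np.full((n_rows, E), np.nan)
    defined = np.zeros((n_rows, E), dtype=bool)
    if emb.standardise:
        logger.info("standardising each variable (z-score) before embedding")
    for j, coord in enumerate(emb.coords):
        y = diffs[coord.variable].values
        if emb.standardise:
            sd = y.std()
            y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        lo, hi = coord.lag, min(n_rows, L + coord.lag)
        values[lo:hi, j] = y[: hi - lo]
        defined[lo:hi, j] = True
    return LagMatrix(
        E=E, values=values, defined=defined, L=L, mode=differencing, span=emb.m + 1
    )


def multivariate_library(
    emb: MultivariateEmbedding,
    t_star: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    differencing: str = "first_difference",
    purpose: str = "evaluation",
) -> Library:
    """Library for a multivariate focal point (index rules driven by ``m+1``)."""
    lag = build_multivariate_matrix(emb, differencing)
    return construct_library(lag, t_star, policy, purpose=purpose)
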