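"""Delay embedding of a univariate time series.

Converts a raw series ``N_t`` (1-based, ``t = 1..T``) into first differences
``Y_t = N_{t+1} - N_t`` and the lagged state-space matrix ``X`` whose row
``t`` is ``x_t = (Y_t, Y_{t-1}, ..., Y_{t-E+1})``.  Cells that would index
outside ``1..L`` (with ``L`` the number of difference values) are explicitly
flagged as undefined rather than silently dropped; every downstream index
rule is driven by those flags.

All public indices are 1-based.  Internal numpy storage is 0-based and never
leaks through the API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "DiffSeries",
    "LagMatrix",
    "SeriesTooShortError",
    "first_difference",
    "passthrough",
    "undifference",
    "build_lag_matrix",
]

#: Allowed differencing modes.
DIFFERENCING_MODES = ("first_difference", "none")


class SeriesTooShortError(ValueError):
    """The series is too short for the requested operation."""


@dataclass(frozen=True)
class TimeSeries:
    """A univariate series of real values indexed ``t = 1..T``.

    Values may be any finite reals (already-differenced input is legal);
    missing values (NaN) are rejected because downstream index bookkeeping
    does not treat gaps.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("TimeSeries expects a 1-d sequence of values")
        if arr.size < 1:
            raise SeriesTooShortError("TimeSeries must contain at least one value")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
            raise ValueError(
                f"non-finite value at t={bad}: missing/inf values are not supported"
            )
        object.__setattr__(self, "values", arr)

    @property
    def T(self) -> int:
        return int(self.values.size)

    def at(self, t: int) -> float:
        """Value ``N_t`` for 1-based ``t``."""
        if not 1 <= t <= self.T:
            raise IndexError(f"t={t} outside 1..{self.T}")
        return float(self.values[t - 1])

    def __len__(self) -> int:
        return self.T

    def __iter__(self) -> Iterator[float]:
        return iter(self.values.tolist())


@dataclass(frozen=True)
class DiffSeries:
    """The (optionally first-differenced) working series ``Y_t``.

    ``mode="first_difference"`` gives ``Y_t = N_{t+1} - N_t`` for
    ``t = 1..T-1``; ``mode="none"`` passes values through, ``Y_t = N_t`` for
    ``t = 1..T``.  ``L`` is the number of defined ``Y`` values.
    """

    values: np.ndarray
    source_T: int
    mode: str = "first_difference"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if self.mode not in DIFFERENCING_MODES:
            raise ValueError(f"unknown differencing mode {self.mode!r}")
        expected = self.source_T - 1 if self.mode == "first_difference" else self.source_T
        if arr.size != expected:
            raise ValueError(
                f"DiffSeries length {arr.size} inconsistent with source_T={self.source_T} "
                f"and mode={self.mode!r} (expected {expected})"
            )

    @property
    def L(self) -> int:
        """Number of defined ``Y`` values (``T-1`` when first-differenced)."""
        return int(self.values.size)

    def at(self, t: int) -> float:
        """Value ``Y_t`` for 1-based ``t``."""
        if not 1 <= t <= self.L:
            raise IndexError(f"t={t} outside 1..{self.L}")
        return float(self.values[t - 1])


def first_difference(series: TimeSeries) -> DiffSeries:
    """Return ``Y_t = N_{t+1} - N_t`` for ``t = 1..T-1``.

    Raises
    ------
    SeriesTooShortError
        If ``T < 2`` (nothing to difference).
    """
    if series.T < 2:
        raise SeriesTooShortError("need T >= 2 to first-difference a series")
    return DiffSeries(np.diff(series.values), source_T=series.T, mode="first_difference")


def passthrough(series: TimeSeries) -> DiffSeries:
    """Skip differencing: ``Y_t = N_t`` for ``t = 1..T``."""
    return DiffSeries(series.values.copy(), source_T=series.T, mode="none")


def make_diff(series: TimeSeries, differencing: str = "first_difference") -> DiffSeries:
    """Dispatch on the differencing switch."""
    if differencing == "first_difference":
        return first_difference(series)
    if differencing == "none":
        return passthrough(series)
    raise ValueError(f"unknown differencing mode {differencing!r}")


def undifference(y_hat: float, n_last: float) -> float:
    """Invert first-differencing for one step: ``N-hat = Y-hat + N_last``."""
    if not (math.isfinite(y_hat) and math.isfinite(n_last)):
        raise ValueError("undifference requires finite inputs")
    return y_hat + n_last


@dataclass(frozen=True)
class LagMatrix:
    """The ``T x E`` lag matrix ``X`` with explicit undefined cells.

    Cell ``(t, j)`` (1-based row ``t``, column ``j = 1..E``) holds
    ``Y_{t-j+1}`` whenever ``1 <= t-j+1 <= L``, and is undefined otherwise.
    ``span`` is the width of the look-ahead exclusion window used by library
    construction; it equals ``E`` for a univariate embedding with consecutive
    lags and ``m+1`` (maximum lag plus one) for a general multivariate
    embedding.  Column 1 always holds the prediction target at lag 0.
    """

    E: int
    values: np.ndarray        # (n_rows, E), np.nan in undefined cells
    defined: np.ndarray       # (n_rows, E) boolean mask
    L: int                    # number of defined target values Y_1..Y_L
    mode: str                 # differencing mode of the underlying series
    span: int = field(default=0)

    def __post_init__(self) -> None:
        if self.span == 0:
            object.__setattr__(self, "span", self.E)

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    def is_defined_row(self, t: int) -> bool:
        if not 1 <= t <= self.n_rows:
            return False
        return bool(self.defined[t - 1].all())

    @property
    def defined_rows(self) -> range:
        """The fully defined rows, ``{first_defined .. L}`` (1-based).

        Computed from the per-cell flags, never from index literals, so the
        no-differencing mode and multivariate lag layouts work unchanged.
        """
        full = self.defined.all(axis=1)
        idx = np.flatnonzero(full)
        if idx.size == 0:
            return range(1, 1)
        first, last = int(idx[0]) + 1, int(idx[-1]) + 1
        return range(first, last + 1)

    def row(self, t: int) -> np.ndarray:
        """Realised state vector ``x_t`` (copies; NaN marks undefined cells)."""
        if not 1 <= t <= self.n_rows:
            raise IndexError(f"t={t} outside 1..{self.n_rows}")
        return self.values[t - 1].copy()

    def target(self, t: int) -> float:
        """The lag-0 target value ``Y_t`` (column 1 of row ``t``)."""
        if not 1 <= t <= self.L:
            raise IndexError(f"target Y_{t} undefined (valid t: 1..{self.L})")
        return float(self.values[t - 1, 0])

    def to_frame(self):
        """Export as a pandas DataFrame with ``'x'`` in undefined cells."""
        import pandas as pd

        cols = [f"Y_t-{j}" if j else "Y_t" for j in range(self.E)]
        out = pd.DataFrame(
            self.values, index=pd.RangeIndex(1, self.n_rows + 1, name="t"), columns=cols
        ).astype(object)
        out[~self.defined] = "x"
        return out


def build_lag_matrix(diff: DiffSeries, E: int) -> LagMatrix:
    """Assemble the lag matrix for embedding dimension ``E``.

    Row ``t`` runs over ``1..T`` (the raw-series length), so with
    first-differencing the final row is present but flagged undefined,
    mirroring the bookkeeping needed to forecast past the data.
    """
    L = diff.L
    if not 1 <= E <= L:
        raise ValueError(f"E={E} outside valid range 1..{L}")
    n_rows = diff.source_T
    values = np.full((n_rows, E), np.nan)
    defined = np.zeros((n_rows, E), dtype=bool)
    y = diff.values
    for j in range(E):  # column j+1 holds Y_{t-j}
        lo, hi = j, min(n_rows, L + j)
        values[lo:hi, j] = y[: hi - lo]
        defined[lo:hi, j] = True
    return LagMatrix(E=E, values=values, defined=defined, L=L, mode=diff.mode)
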