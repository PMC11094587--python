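"""Focal-time validity and the library of candidate nearest neighbours.

Two pieces of bookkeeping that most simplex implementations leave implicit:

1. which times ``t*`` may serve as focal points at all, given the embedding
   dimension (their lag vectors must not reach before the start of the series
   or past its end); and
2. which embedded points are eligible to be nearest neighbours of ``x_{t*}``
   — the *library* — after four exclusions:

   (a) the focal point itself;
   (b) rows with undefined cells;
   (c) rows whose successor target is unknown (we must see where a neighbour
       goes one step later);
   (d) rows whose coordinates contain the very value being predicted, i.e.
       ``t in {t*+1, ..., t*+span}``.

The default policy applies (a)-(d).  The ``radius`` policy replaces (d) with
a symmetric temporal exclusion ``|t - t*| <= k`` (the behaviour of other
toolkits' exclusion-radius option; ``k = 0`` keeps every temporal neighbour
and drops only the focal row), while (a)-(c) always apply.

The library size admits a closed form, :func:`library_size`; the constructive
count and the formula are required to agree everywhere and are cross-checked
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .embedding import LagMatrix

__all__ = [
    "ExclusionPolicy",
    "Library",
    "EmptyLibraryError",
    "valid_focal_times",
    "construct_library",
    "library_size",
]

Purpose = Literal["evaluation", "forecast"]


class EmptyLibraryError(ValueError):
    """No candidate neighbours survive the exclusions."""


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which rows to exclude from the library besides (a)-(c).

    mode="default"
        Apply condition (d): exclude ``t* + 1 .. t* + span``.
    mode="radius"
        Exclude temporal neighbours ``|t - t*| <= radius_k`` instead of (d).
    """

    mode: str = "default"
    radius_k: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("default", "radius"):
            raise ValueError(f"unknown exclusion mode {self.mode!r}")
        if self.radius_k < 0:
            raise ValueError("radius_k must be non-negative")

    @classmethod
    def default(cls) -> "ExclusionPolicy":
        return cls(mode="default")

    @classmethod
    def radius(cls, k: int) -> "ExclusionPolicy":
        return cls(mode="radius", radius_k=k)

    @classmethod
    def parse(cls, text: str) -> "ExclusionPolicy":
        """Parse ``"default"`` or ``"radius:<k>"`` (CLI syntax)."""
        if text == "default":
            return cls.default()
        if text.startswith("radius"):
            _, _, k = text.partition(":")
            return cls.radius(int(k) if k else 0)
        raise ValueError(f"cannot parse exclusion policy {text!r}")

    def __str__(self) -> str:
        return "default" if self.mode == "default" else f"radius:{self.radius_k}"


@dataclass(frozen=True)
class Library:
    """The candidate-neighbour set for one focal time."""

    E: int
    t_star: int
    member_times: tuple[int, ...]  # ascending 1-based time indices

    @property
    def size(self) -> int:
        return len(self.member_times)

    def __contains__(self, t: int) -> bool:
        return t in set(self.member_times)


def valid_focal_times(
    T: int,
    E: int,
    purpose: Purpose = "evaluation",
    differencing: str = "first_difference",
) -> range:
    """Allowable focal times ``t*`` for a univariate embedding.

    With first-differencing: ``{E..T-2}`` for evaluation (the prediction must
    be comparable with an observed value) and ``{E..T-1}`` for forecasting
    one step past the data.  Without differencing both windows shift up by
    one since ``Y_T`` then exists.
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    L = T - 1 if differencing == "first_difference" else T
    hi = L - 1 if purpose == "evaluation" else L
    if E > hi:
        raise ValueError(
            f"series of length T={T} too short for E={E} ({purpose}): "
            f"no valid focal times"
        )
    return range(E, hi + 1)


def _focal_window(lag: LagMatrix, purpose: Purpose) -> range:
    rows = lag.defined_rows
    if len(rows) == 0:
        raise ValueError("lag matrix has no fully defined rows")
    hi = lag.L - 1 if purpose == "evaluation" else lag.L
    return range(rows.start, hi + 1)


def construct_library(
    lag: LagMatrix,
    t_star: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    purpose: Purpose = "evaluation",
) -> Library:
    """Build the library for focal time ``t_star`` under ``policy``.

    Candidates are the fully defined rows whose successor target is known;
    exclusions follow the policy (see module docstring).  Membership is
    returned in ascending time order — downstream ranking must not rely on
    this ordering.
    """
    window = _focal_window(lag, purpose)
    if t_star not in window:
        raise ValueError(
            f"t*={t_star} is not a valid focal time for {purpose} "
            f"(valid: {window.start}..{window.stop - 1})"
        )
    span = lag.span
    members = []
    for t in lag.defined_rows:
        if t + 1 > lag.L:          # (c) successor target Y_{t+1} unknown
            continue
        if t == t_star:            # (a) focal row
            continue
        if policy.mode == "default":
            if t_star + 1 <= t <= t_star + span:   # (d) contains Y_{t*+1}
                continue
        else:
            if abs(t - t_star) <= policy.radius_k:
                continue
        members.append(t)
    if not members:
        raise EmptyLibraryError(
            f"library empty for t*={t_star}, E={lag.E} (series too short or E too large)"
        )
    return Library(E=lag.E, t_star=t_star, member_times=tuple(members))


def library_size(T: int, E: int, t_star: int) -> int:
    """Closed-form library size for the default policy (first-differenced).

    Equals ``T - 2(E+1)`` throughout the constant region ``E <= t* <= T-E-2``
    and climbs by one per step over the last ``E`` focal times, reaching
    ``T - 2(E+1) + E`` at ``t* = T-2``.  Note: some published statements of
    the constant drop the parentheses (printing ``T - 2E + 1``); the worked
    sizes force ``T - 2(E+1)``.

    Always equals ``construct_library(...).size`` under the default policy.
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    if not E <= t_star <= T - 2:
        raise ValueError(f"t*={t_star} invalid for T={T}, E={E} (valid: {E}..{T - 2})")
    base = T - 2 * (E + 1)
    if t_star <= T - E - 2:
        size = base
    else:
        size = base + (t_star - (T - E - 2))
    if size <= 0:
        raise EmptyLibraryError(f"library empty for T={T}, E={E}, t*={t_star}")
    return size
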