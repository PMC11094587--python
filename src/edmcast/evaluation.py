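"""Leave-one-out skill evaluation and embedding-dimension selection.

For each valid focal time the simplex prediction is compared with the value
actually observed one step later; forecast skill is the Pearson correlation
``rho`` between the two, computed either on the working (differenced) scale
or on the raw scale after undifferencing each prediction.  The embedding
dimension with the highest differenced-scale ``rho`` is selected (ties go to
the smallest E — parsimony).

A caution worth repeating: high correlation on the differenced scale does
not imply high correlation on the raw scale; both are always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .embedding import TimeSeries, build_lag_matrix, make_diff
from .library import (
    EmptyLibraryError,
    ExclusionPolicy,
    Library,
    construct_library,
    valid_focal_times,
)
from .simplex import PredictionResult, predict_from_library, predict_point

__all__ = [
    "ZeroVarianceError",
    "EmbeddingEvaluation",
    "EvaluationResult",
    "pearson_rho",
    "evaluate_embedding",
    "select_E",
    "split_half_evaluate",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined when one side has zero variance."""


def pearson_rho(observed, predicted) -> float:
    """Pearson correlation between paired observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs for a meaningful correlation")
    for name, arr in (("observed", obs), ("predicted", pred)):
        if np.ptp(arr) == 0:
            raise ZeroVarianceError(f"{name} values have zero variance; rho undefined")
    oc = obs - obs.mean()
    pc = pred - pred.mean()
    return float(np.sum(oc * pc) / np.sqrt(np.sum(oc**2) * np.sum(pc**2)))


@dataclass(frozen=True)
class EmbeddingEvaluation:
    """All leave-one-out predictions for one embedding dimension."""

    E: int
    predictions: tuple[PredictionResult, ...]
    rho_Y: float
    rho_N: Optional[float]
    valid_tstars: tuple[int, ...]


@dataclass(frozen=True)
class EvaluationResult:
    per_E: dict[int, EmbeddingEvaluation]
    E_star: int
    rho_star: float


def _loo_predictions(
    series: TimeSeries,
    E: int,
    policy: ExclusionPolicy,
    differencing: str,
    k: Optional[int],
) -> tuple[list[PredictionResult], list[int]]:
    """Simplex predictions at every valid evaluation focal time.

    Focal times whose library collapses (tiny series edge case) are dropped
    from the pairing and logged, never imputed.
    """
    diff = make_diff(series, differencing)
    lag = build_lag_matrix(diff, E)
    tstars = valid_focal_times(series.T, E, "evaluation", differencing)
    preds, used = [], []
    for t_star in tstars:
        try:
            preds.append(predict_point(lag, t_star, policy=policy, k=k))
        except (EmptyLibraryError, ValueError) as exc:
            logger.info("skipping t*=%d for E=%d: %s", t_star, E, exc)
            continue
        used.append(t_star)
    return preds, used


def _paired_rho(
    series: TimeSeries,
    preds: Iterable[PredictionResult],
    differencing: str,
    scale: str,
    restrict_to: Optional[set[int]] = None,
) -> float:
    """Correlate predictions with observations on the requested scale.

    scale="Y" pairs ``Y-hat_{t*+1}`` with ``Y_{t*+1}``; scale="N"
    undifferences each prediction (``N-hat_{t*+2} = Y-hat_{t*+1} + N_{t*+1}``)
    and pairs it with ``N_{t*+2}``.
    """
    diff = make_diff(series, differencing)
    obs, est = [], []
    for p in preds:
        if restrict_to is not None and p.focal_t not in restrict_to:
            continue
        t1 = p.focal_t + 1
        if scale == "Y" or differencing == "none":
            obs.append(diff.at(t1))
            est.append(p.y_hat)
        else:
            obs.append(series.at(t1 + 1))
            est.append(p.y_hat + series.at(t1))
    return pearson_rho(obs, est)


def evaluate_embedding(
    series: TimeSeries,
    E: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    scale: str = "Y",
    differencing: str = "first_difference",
    k: Optional[int] = None,
) -> tuple[float, list[PredictionResult]]:
    """Leave-one-out ``rho`` for one embedding dimension.

    Returns the correlation on the requested scale together with the full
    per-focal-time prediction bookkeeping.
    """
    if scale not in ("Y", "N"):
        raise ValueError(f"scale must be 'Y' or 'N', got {scale!r}")
    preds, _ = _loo_predictions(series, E, policy, differencing, k)
    rho = _paired_rho(series, preds, differencing, scale)
    return rho, preds


def select_E(
    series: TimeSeries,
    E_range: Iterable[int],
    policy: ExclusionPolicy = ExclusionPolicy(),
    common_tstar: bool = False,
    differencing: str = "first_difference",
    k: Optional[int] = None,
) -> EvaluationResult:
    """Evaluate a range of embedding dimensions and pick the best.

    ``E_star`` maximises the differenced-scale ``rho``; ties go to the
    smallest E.  With ``common_tstar`` the correlations for every E are
    computed over the intersection of the valid focal-time sets (i.e. the
    most restrictive E's set), removing the small-E advantage of predicting
    extra early points.
    """
    Es = sorted(set(int(E) for E in E_range))
    if not Es:
        raise ValueError("E_range must be non-empty")
    raw: dict[int, tuple[list[PredictionResult], list[int]]] = {}
    for E in Es:
        try:
            raw[E] = _loo_predictions(series, E, policy, differencing, k)
        except ValueError as exc:
            logger.warning("E=%d not evaluable: %s", E, exc)
    if not raw:
        raise ValueError("no embedding dimension in the range could be evaluated")

    restrict: Optional[set[int]] = None
    if common_tstar:
        common = None
        for _, used in raw.values():
            common = set(used) if common is None else common & set(used)
        restrict = common

    per_E: dict[int, EmbeddingEvaluation] = {}
    for E, (preds, used) in raw.items():
        rho_Y = _paired_rho(series, preds, differencing, "Y", restrict)
        rho_N: Optional[float] = None
        if differencing == "first_difference":
            rho_N = _paired_rho(series, preds, differencing, "N", restrict)
        per_E[E] = EmbeddingEvaluation(
            E=E,
            predictions=tuple(preds),
            rho_Y=rho_Y,
            rho_N=rho_N,
            valid_tstars=tuple(used),
        )
    E_star = max(per_E, key=lambda E: (per_E[E].rho_Y, -E))
    return EvaluationResult(per_E=per_E, E_star=E_star, rho_star=per_E[E_star].rho_Y)


def skill_extras(
    series: TimeSeries,
    predictions: Iterable[PredictionResult],
    differencing: str = "first_difference",
) -> dict[str, float]:
    """MAE and RMSE on the working scale.

    Reported alongside rho for diagnostics only; embedding-dimension
    selection uses rho exclusively.
    """
    diff = make_diff(series, differencing)
    err = np.array([p.y_hat - diff.at(p.focal_t + 1) for p in predictions])
    if err.size == 0:
        raise ValueError("no predictions to summarise")
    return {
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err**2).mean())),
    }


def split_half_evaluate(
    series: TimeSeries,
    E: int,
    policy: ExclusionPolicy = ExclusionPolicy(),
    differencing: str = "first_difference",
    k: Optional[int] = None,
) -> float:
    """Use the first half of the series to predict the second half.

    The library is restricted to embedded points (and their successors)
    lying wholly in the first half; focal times are drawn from the second
    half.  Returns ``rho`` on the working scale.
    """
    if series.T < 4 * E + 8:
        raise ValueError(
            f"T={series.T} too short for split-half evaluation at E={E} "
            f"(need T >= {4 * E + 8})"
        )
    diff = make_diff(series, differencing)
    lag = build_lag_matrix(diff, E)
    half = series.T // 2
    first_half = [t for t in lag.defined_rows if t + 1 <= min(half, lag.L)]
    preds = []
    for t_star in range(max(E, half + 1), lag.L):
        full = construct_library(lag, t_star, policy)
        members = tuple(t for t in full.member_times if t in set(first_half))
        if len(members) < (k if k is not None else E + 1):
            continue
        lib = Library(E=E, t_star=t_star, member_times=members)
        preds.append(predict_from_library(lag, lib, k=k))
    if len(preds) < 3:
        raise ValueError("second half too short: fewer than 3 predictions possible")
    return _paired_rho(series, preds, differencing, "Y")
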