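"""S-map: locally weighted linear one-step prediction.

Instead of averaging the destinations of a few nearest neighbours, the S-map
fits a linear map from state vectors to their one-step-ahead targets over
the *entire* library, downweighting distant points exponentially:

    w_t = exp(-theta * d_t / d_mean)

with ``d_t`` the Euclidean distance from the focal point and ``d_mean`` the
mean distance over the library.  ``theta = 0`` weights everything equally
and so reduces to a global linear autoregression; larger ``theta``
localises the fit, tracking state-dependent (nonlinear) dynamics.

The weighted least-squares problem is solved through an SVD with a relative
singular-value cutoff, which tolerates the rank deficiency that small,
collinear libraries can produce.

The library is the identical candidate set used by the simplex (exclusion
conditions shared by construction, not re-derived).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .embedding import LagMatrix, TimeSeries, build_lag_matrix, make_diff
from .evaluation import pearson_rho
from .library import EmptyLibraryError, ExclusionPolicy, Library, construct_library, valid_focal_times

__all__ = ["SmapConfig", "SmapFit", "smap_weights", "smap_predict", "theta_scan"]

#: Relative singular-value cutoff for the rank-tolerant weighted solve.
SVD_RCOND = 1e-10


@dataclass(frozen=True)
class SmapConfig:
    theta: float
    E: int
    policy: ExclusionPolicy = ExclusionPolicy()
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.E < 1:
            raise ValueError("E must be >= 1")


@dataclass(frozen=True)
class SmapFit:
    """Fitted local linear map at one focal time.

    ``coefficients[0]`` is the intercept (0.0 when disabled), followed by one
    coefficient per embedding coordinate, so the prediction is
    ``y_hat = c_0 + sum_j c_j * x_{t*}[j]``.
    """

    focal_t: int
    coefficients: np.ndarray
    y_hat: float
    theta: float


def smap_weights(
    lag: LagMatrix,
    library: Library,
    t_star: int,
    theta: float,
) -> np.ndarray:
    """Exponential locality weights for every library member (library order).

    ``w_t = exp(-theta * d_t / d_mean)``; if the mean distance is zero every
    weight is 1.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if library.size == 0:
        raise EmptyLibraryError("cannot weight an empty library")
    focal = lag.row(t_star)
    members = np.array(library.member_times, dtype=int)
    dists = np.sqrt(np.sum((lag.values[members - 1] - focal) ** 2, axis=1))
    d_mean = dists.mean()
    if d_mean == 0:
        return np.ones_like(dists)
    return np.exp(-theta * dists / d_mean)


def smap_predict(
    lag: LagMatrix,
    t_star: int,
    config: SmapConfig,
    purpose: str = "evaluation",
) -> SmapFit:
    """Fit the weighted linear map at ``t_star`` and evaluate it there.

    Solves ``Y_{psi+1} ~ c_0 + sum_j c_j x_psi[j]`` over all library members
    by weighted least squares (weights from :func:`smap_weights`), using an
    SVD-based solver with relative cutoff ``SVD_RCOND``.
    """
    library = construct_library(lag, t_star, config.policy, purpose=purpose)
    if library.size <= lag.E + 1:
        raise ValueError(
            f"library size {library.size} too small to fit an S-map with "
            f"E={lag.E} (need > E+1 members)"
        )
    w = smap_weights(lag, library, t_star, config.theta)
    members = np.array(library.member_times, dtype=int)
    X = lag.values[members - 1]
    y = np.array([lag.target(int(t) + 1) for t in members])
    if config.intercept:
        X = np.column_stack([np.ones(len(members)), X])
    sw = np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=SVD_RCOND)
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("weighted solve produced non-finite coefficients")
    focal = lag.row(t_star)
    if config.intercept:
        coefficients = coef
    else:
        coefficients = np.concatenate([[0.0], coef])
    y_hat = float(coefficients[0] + coefficients[1:] @ focal)
    return SmapFit(
        focal_t=t_star, coefficients=coefficients, y_hat=y_hat, theta=config.theta
    )


def theta_scan(
    series: TimeSeries,
    E: int,
    thetas: Iterable[float],
    policy: ExclusionPolicy = ExclusionPolicy(),
    differencing: str = "first_difference",
) -> dict[float, float]:
    """Leave-one-out working-scale ``rho`` for each nonlinearity ``theta``."""
    diff = make_diff(series, differencing)
    lag = build_lag_matrix(diff, E)
    tstars = valid_focal_times(series.T, E, "evaluation", differencing)
    out: dict[float, float] = {}
    for theta in thetas:
        config = SmapConfig(theta=float(theta), E=E, policy=policy)
        obs, est = [], []
        for t_star in tstars:
            try:
                fit = smap_predict(lag, t_star, config)
            except (EmptyLibraryError, ValueError):
                continue
            obs.append(diff.at(t_star + 1))
            est.append(fit.y_hat)
        out[float(theta)] = pearson_rho(obs, est)
    return out
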