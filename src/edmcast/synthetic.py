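"""Seed-deterministic fixture generators and the reference-series loader.

``generate_spiky_series`` produces boom-bust dynamics — values hovering at a
low base level with occasional large spikes followed by immediate crashes —
via a Ricker-type map with sporadic recruitment pulses.  This is a stand-in
with the right phenomenology for exercising the embedding/simplex machinery,
not a reproduction of any particular population model.

``load_reference_series`` reads the published 100-step example series used
by the golden-value tests.  Redistribution rights for that file are
uncertain, so it is not bundled; the loader fingerprints the first four
differenced values and the final raw value so tests can never silently run
against the wrong data.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embedding import TimeSeries, first_difference

__all__ = [
    "SpikySeriesConfig",
    "generate_spiky_series",
    "generate_linear_recurrence",
    "load_reference_series",
    "locate_reference_series",
    "ReferenceSeriesError",
]

#: Environment variable that may point at the reference-series CSV.
REFERENCE_ENV_VAR = "EDMCAST_REFERENCE_SERIES"

#: Known fingerprints of the reference series (values as published, 3 d.p.).
REFERENCE_Y_HEAD = (-0.057, 0.059, 5.241, -4.854)
REFERENCE_N_LAST = 0.060
REFERENCE_T = 100
_FINGERPRINT_ATOL = 5.1e-4  # published to 3 d.p.


@dataclass(frozen=True)
class SpikySeriesConfig:
    """Parameters of the boom-bust generator; the seed fully determines output."""

    T: int = 100
    base_level: float = 0.3
    spike_rate: float = 0.1
    spike_scale: float = 4.0
    noise_sd: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        if self.T < 10:
            raise ValueError("T must be >= 10")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must be a probability in [0, 1]")
        if self.base_level <= 0 or self.spike_scale < 0 or self.noise_sd < 0:
            raise ValueError("base_level must be > 0; scales must be >= 0")

    def metadata(self) -> dict:
        """Config echo for sidecar output."""
        return asdict(self)


def generate_spiky_series(config: SpikySeriesConfig) -> TimeSeries:
    """Boom-bust series from a Ricker-type map with recruitment pulses.

    ``N_{t+1} = N_t * exp(r * (1 - N_t / base_level) + eps_t) + pulse_t``
    with ``r = 0.2`` (weak density dependence keeps crash landings near the
    base level), ``eps_t ~ Normal(0, noise_sd)`` and, with probability
    ``spike_rate``, an additive pulse of order ``spike_scale``.  All values
    stay strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    r = 0.2
    n = np.empty(config.T)
    n[0] = config.base_level
    for t in range(config.T - 1):
        eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        nxt = n[t] * np.exp(r * (1.0 - n[t] / config.base_level) + eps)
        if config.spike_rate > 0 and rng.random() < config.spike_rate:
            nxt += config.spike_scale * (0.8 + 0.4 * rng.random())
        n[t + 1] = nxt
    return TimeSeries(n)


def generate_linear_recurrence(
    coeffs: Sequence[float],
    init: Sequence[float],
    T: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Exact linear autoregression ``v_t = sum_j coeffs[j] * v_{t-1-j}``.

    ``init`` seeds the first ``len(coeffs)`` values.  With ``noise_sd = 0``
    the recurrence is exact, which makes it the canonical fixture for S-map
    coefficient-recovery tests (run with differencing disabled).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    init = np.asarray(init, dtype=float)
    if coeffs.ndim != 1 or init.shape != coeffs.shape:
        raise ValueError("init must have the same length as coeffs")
    p = coeffs.size
    if T < p:
        raise ValueError(f"T={T} shorter than the recurrence order {p}")
    rng = np.random.default_rng(seed)
    v = np.empty(T)
    v[:p] = init
    for t in range(p, T):
        v[t] = float(coeffs @ v[t - 1 : t - 1 - p if t - 1 - p >= 0 else None : -1])
        if noise_sd > 0:
            v[t] += rng.normal(0.0, noise_sd)
    return TimeSeries(v)


class ReferenceSeriesError(ValueError):
    """The candidate reference file fails a fingerprint or format check."""


def locate_reference_series() -> Optional[Path]:
    """Find the reference-series CSV, if the user has provided one.

    Checks the ``EDMCAST_REFERENCE_SERIES`` environment variable, then
    ``data/reference_series.csv`` relative to the working directory and to
    the repository root (two levels above this package when run from a
    source checkout).  Returns ``None`` when absent.
    """
    env = os.environ.get(REFERENCE_ENV_VAR)
    candidates = []
    if env:
        candidates.append(Path(env))
    candidates.append(Path("data") / "reference_series.csv")
    here = Path(__file__).resolve()
    candidates.append(here.parents[3] / "data" / "reference_series.csv")
    for path in candidates:
        if path.is_file():
            return path
    return None


def load_reference_series(path) -> TimeSeries:
    """Load and fingerprint-validate the published 100-step example series.

    The CSV may carry an ``N`` column (raw values) or a ``Y`` column (first
    differences); whichever is present is validated against the published
    fingerprints, failing loudly with the offending check named.  A ``Y``-only
    file cannot be undifferenced without the missing constant, so ``N`` is
    required for raw-scale work.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    cols = {c.lower(): c for c in df.columns}
    if "n" not in cols:
        raise ReferenceSeriesError(
            f"{path}: expected a column named 'N' (raw series); found {list(df.columns)}"
        )
    n_vals = df[cols["n"]].to_numpy(dtype=float)
    n_vals = n_vals[~np.isnan(n_vals)]
    if n_vals.size != REFERENCE_T:
        raise ReferenceSeriesError(
            f"{path}: expected {REFERENCE_T} values, found {n_vals.size}"
        )
    series = TimeSeries(n_vals)
    y = first_difference(series).values
    for i, expected in enumerate(REFERENCE_Y_HEAD, start=1):
        if abs(y[i - 1] - expected) > _FINGERPRINT_ATOL:
            raise ReferenceSeriesError(
                f"{path}: fingerprint mismatch at Y_{i}: got {y[i - 1]:.6g}, "
                f"expected {expected} (to 3 d.p.)"
            )
    if abs(series.at(REFERENCE_T) - REFERENCE_N_LAST) > _FINGERPRINT_ATOL:
        raise ReferenceSeriesError(
            f"{path}: fingerprint mismatch at N_{REFERENCE_T}: got "
            f"{series.at(REFERENCE_T):.6g}, expected {REFERENCE_N_LAST} (to 3 d.p.)"
        )
    if "y" in cols:
        y_file = df[cols["y"]].to_numpy(dtype=float)
        y_file = y_file[~np.isnan(y_file)]
        if y_file.size >= REFERENCE_T - 1 and not np.allclose(
            y_file[: REFERENCE_T - 1], y, atol=_FINGERPRINT_ATOL
        ):
            raise ReferenceSeriesError(
                f"{path}: Y column inconsistent with first-differenced N column"
            )
    return series
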