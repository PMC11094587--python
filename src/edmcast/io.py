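"""CSV readers/writers and the run configuration shared by the CLI.

Data files are plain CSV with a header.  Input series carry an optional
integer ``t`` column (which must be gapless when present) and a value column
named ``N`` — or ``Y`` when the values are already differenced and the run
uses ``differencing: none``.  Output files are written at full double
precision (Python's shortest round-trip repr) so independent implementations
can be diffed cell by cell; rounding happens only in human-readable logs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .embedding import TimeSeries
from .library import ExclusionPolicy

__all__ = ["RunConfig", "read_series_csv", "write_series_csv", "write_frame"]


def read_series_csv(path, column: Optional[str] = None) -> TimeSeries:
    """Read a univariate series from CSV.

    Picks the ``N`` column (or ``Y`` as a fallback for pre-differenced
    input) unless ``column`` names one explicitly.  A ``t`` column, when
    present, must be a gapless integer sequence.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    if "t" in df.columns:
        t = df["t"].to_numpy()
        if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValueError(f"{path}: 't' column has gaps or is unsorted")
    if column is None:
        for cand in ("N", "Y"):
            if cand in df.columns:
                column = cand
                break
        else:
            raise ValueError(
                f"{path}: no 'N' or 'Y' column found (columns: {list(df.columns)})"
            )
    elif column not in df.columns:
        raise ValueError(f"{path}: no column named {column!r}")
    return TimeSeries(df[column].to_numpy(dtype=float))


#: printf format guaranteeing float64 round-trips through text
_FULL_PRECISION = "%.17g"


def write_series_csv(path, series: TimeSeries, column: str = "N") -> None:
    df = pd.DataFrame({"t": np.arange(1, series.T + 1), column: series.values})
    df.to_csv(path, index=False, float_format=_FULL_PRECISION)


def write_frame(path, frame: pd.DataFrame) -> None:
    """Write a data frame at full double precision."""
    frame.to_csv(path, index=False, float_format=_FULL_PRECISION)


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Every CLI flag has an equivalent field here; CLI values override the
    config file.  Serialisable to/from YAML.
    """

    input: str = ""
    differencing: str = "first_difference"
    E: Optional[int] = None
    E_min: int = 2
    E_max: int = 6
    policy: str = "default"
    neighbours: Optional[int] = None
    thetas: Sequence[float] = field(default_factory=tuple)
    remedy: str = "none"
    scale: str = "Y"
    common_tstar: bool = False
    output_dir: str = "edmcast_out"
    seed: int = 0
    log_level: str = "INFO"

    def exclusion_policy(self) -> ExclusionPolicy:
        return ExclusionPolicy.parse(self.policy)

    def E_values(self) -> list[int]:
        if self.E is not None:
            return [self.E]
        return list(range(self.E_min, self.E_max + 1))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.thetas:
            cfg.thetas = tuple(float(x) for x in cfg.thetas)
        return cfg

    def merged(self, **overrides) -> "RunConfig":
        """Return a copy with non-None overrides applied (CLI wins)."""
        data = dataclasses.asdict(self)
        for key, value in overrides.items():
            if value is not None:
                data[key] = value
        return RunConfig(**data)
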