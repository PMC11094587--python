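import numpy as np
import pytest

from edmcast import (
    SpikySeriesConfig,
    TimeSeries,
    generate_spiky_series,
    load_reference_series,
    locate_reference_series,
)


@pytest.fixture(scope="session")
def spiky_series() -> TimeSeries:
    """Default boom-bust fixture series (seed-deterministic)."""
    return generate_spiky_series(SpikySeriesConfig())


@pytest.fixture
def random_series() -> TimeSeries:
    rng = np.random.default_rng(1234)
    return TimeSeries(rng.normal(size=100))


@pytest.fixture(scope="session")
def reference_series() -> TimeSeries:
    """The published 100-step example series; skips when not provided.

    Supply it via the EDMCAST_REFERENCE_SERIES environment variable or as
    data/reference_series.csv (CSV with an N column, 100 values).
    """
    path = locate_reference_series()
    if path is None:
        pytest.skip(
            "reference series not available: provide the published 100-step "
            "example series as data/reference_series.csv or point "
            "EDMCAST_REFERENCE_SERIES at it (golden-value tests only)"
        )
    return load_reference_series(path)
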