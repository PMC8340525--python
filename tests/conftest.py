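from datetime import datetime, timedelta

import pytest

from bpviz.model import BPMeasurement, DisplayConfig, Source
from bpviz.synthetic import SimParams, simulate_bp_series

T0 = datetime(2021, 7, 1)


@pytest.fixture
def t0():
    return T0


@pytest.fixture
def two_month_config():
    return DisplayConfig(window=(T0, T0 + timedelta(days=62)))


@pytest.fixture
def two_month_series():
    """Twice-daily home readings over July-August, deterministic."""
    params = SimParams(seed=7)
    return simulate_bp_series(params, (T0, T0 + timedelta(days=62)))


def reading(hours=0.0, sbp=120.0, dbp=80.0, source=Source.HOME, confirmed=False):
    return BPMeasurement(
        timestamp=T0 + timedelta(hours=hours),
        systolic=sbp,
        diastolic=dbp,
        source=source,
        confirmed=confirmed,
    )
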