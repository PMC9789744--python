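import numpy as np
import pytest

from dvos import ChromophoreSeries, build_protocol
from dvos.protocol import TrialWindow


@pytest.fixture(scope="session")
def schedule():
    return build_protocol()


@pytest.fixture
def trial(schedule):
    return schedule.trials[0]


def series_from_hbt(t, hbt, hbo2_fraction=0.5):
    """Wrap a raw HbT curve as a chromophore series for feature tests."""
    t = np.asarray(t, dtype=float)
    hbt = np.asarray(hbt, dtype=float)
    return ChromophoreSeries(
        timestamps_s=t,
        dHbO2_uM=hbo2_fraction * hbt,
        dHb_uM=(1.0 - hbo2_fraction) * hbt,
    )


@pytest.fixture
def make_series():
    return series_from_hbt


@pytest.fixture
def simple_window():
    """An 80 s trial window starting at t=0 for analytic test curves."""
    return TrialWindow(
        pressure_mmhg=60.0,
        inflation_onset_s=0.0,
        inflation_end_s=10.0,
        deflation_s=70.0,
        window_end_s=80.0,
    )
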