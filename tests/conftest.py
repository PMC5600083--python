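import numpy as np
import pytest

from volbandit.ideal_observer import run_observer
from volbandit.schedule import Schedule, ScheduleConfig, TrialRecord, build_schedule


@pytest.fixture(scope="session")
def short_schedule():
    return build_schedule(ScheduleConfig("short", seed=11))


@pytest.fixture(scope="session")
def long_schedule():
    return build_schedule(ScheduleConfig("long", seed=11))


@pytest.fixture(scope="session")
def short_trajectory(short_schedule):
    return run_observer(short_schedule)


def make_schedule(rewarded, mag_a, condition=None, choices=None):
    """Hand-build a schedule from explicit per-trial values (test helper)."""
    n = len(rewarded)
    condition = condition or ["stable"] * n
    trials = [
        TrialRecord(
            index=i + 1,
            rewarded_option=rewarded[i],
            magnitude_a=mag_a[i],
            magnitude_b=100 - mag_a[i],
            condition=condition[i],
            block_id=1,
            choice=None if choices is None else choices[i],
        )
        for i in range(n)
    ]
    return Schedule(trials=trials, switch_points=[])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
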