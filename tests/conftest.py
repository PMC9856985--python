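import numpy as np
import pandas as pd
import pytest

from restwatch.io_formats import BedSchedule, EpochSeries
from restwatch.synthetic import CohortSpec, generate_cohort

NOON = pd.Timestamp("2019-03-04 12:00")


def make_series(counts, participant_id="P01", start=NOON):
    return EpochSeries(participant_id=participant_id, start_time=start, counts=counts)


def make_schedule(intervals, participant_id="P01"):
    return BedSchedule(participant_id=participant_id, intervals=intervals)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190304)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-participant, 4-day cohort for fast integration tests."""
    return generate_cohort(CohortSpec(n_participants=10, days_per_participant=4, seed=7))


@pytest.fixture(scope="session")
def two_night_setup():
    """Two-night recording: known in-bed/out-of-bed structure for metric tests.

    48 h from noon; nights 23:00-07:00 both days.
    """
    counts = np.zeros(2 * 1440)
    start = NOON
    iv = [
        (start + pd.Timedelta(hours=11), start + pd.Timedelta(hours=19)),
        (start + pd.Timedelta(hours=35), start + pd.Timedelta(hours=43)),
    ]
    return counts, start, iv
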