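import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import actipat as ap
from actipat.epochs import ActivityLabel, EpochSeries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

W, ST, SI, L = (
    int(ActivityLabel.WALKING),
    int(ActivityLabel.STANDING),
    int(ActivityLabel.SITTING),
    int(ActivityLabel.LYING),
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(labels, pid="p1", epoch_seconds=60, start="2018-03-05 00:00:00"):
    return EpochSeries(
        participant_id=pid,
        start_time=pd.Timestamp(start),
        labels=np.asarray(labels, dtype=np.int8),
        epoch_seconds=epoch_seconds,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-conditions cohort (163 participants, 2 wear days)."""
    return ap.simulate_cohort(ap.default_config_from_paper(seed=11))


@pytest.fixture(scope="session")
def small_cohort_files(tmp_path_factory):
    """A small written cohort for CLI / IO round-trip tests."""
    cfg = ap.default_config_from_paper(n_participants=16, wear_days=1, seed=7)
    cohort = ap.simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("cohort")
    paths = cohort.write(out)
    return cohort, paths
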