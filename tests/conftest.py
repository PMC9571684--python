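import numpy as np
import pandas as pd
import pytest

from wearcontext.features import load_catalogue
from wearcontext.synthetic import CohortSpec
from wearcontext.timeseries import Channel, Recording

T0 = pd.Timestamp("2022-03-10 09:00:00")


def make_recording(duration_s: float = 60.0, seed: int = 0,
                   start: pd.Timestamp = T0, subject: str = "S000") -> Recording:
    """Small complete five-channel recording of iid-noise signals."""
    rng = np.random.default_rng(seed)
    chans = {}
    for name, rate in (("accel_x", 32), ("accel_y", 32), ("accel_z", 32),
                       ("gsr", 4), ("skin_temp", 4)):
        n = int(duration_s * rate)
        base = 2.0 if name == "gsr" else (31.0 if name == "skin_temp" else 0.0)
        chans[name] = Channel(name, float(rate), start,
                              base + np.abs(rng.normal(0, 0.1, n)))
    return Recording(subject, chans)


@pytest.fixture(scope="session")
def hourly_catalogue():
    return load_catalogue("hourly")


@pytest.fixture(scope="session")
def har_catalogue():
    return load_catalogue("har")


@pytest.fixture(scope="session")
def fast_spec():
    """Cohort spec for quick rendering tests (defaults, 1 subject, 1 day)."""
    return CohortSpec(n_subjects=1, n_days=1, seed=11)


@pytest.fixture(scope="session")
def har_mini_rows(fast_spec, har_catalogue):
    """Small labelled HAR window set (2 subjects) shared across tests."""
    from wearcontext.pipeline import make_har_training_cohort

    return make_har_training_cohort(fast_spec, 3, seed=77, repeats=1,
                                    catalogue=har_catalogue)


@pytest.fixture(scope="session")
def har_mini_model(har_mini_rows):
    from wearcontext.har import HarConfig, train_har

    return train_har(har_mini_rows, HarConfig(depth_grid=(4,), n_folds=2,
                                              n_estimators=60, seed=1))
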