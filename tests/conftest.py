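import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import luxwear as lw

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def minute_index():
    def make(n, start="2025-01-06 00:00"):
        return pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="min")

    return make


def make_stream(n=60, start="2025-01-06 00:00", lux=None, medi=None, tat=None,
                orientation=None, participant_id="T", timestamps=None):
    if timestamps is None:
        timestamps = pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="min")
    n = len(timestamps)
    return lw.RecordingStream(
        participant_id=participant_id,
        timestamps=pd.DatetimeIndex(timestamps),
        photopic_lux=np.full(n, 100.0) if lux is None else np.asarray(lux, float),
        medi_lux=np.full(n, 80.0) if medi is None else np.asarray(medi, float),
        tat_count=np.zeros(n, dtype=int) if tat is None else np.asarray(tat, int),
        orientation_code=(
            np.full(n, 2, dtype=int) if orientation is None
            else np.asarray(orientation, int)
        ),
    )


@pytest.fixture
def stream_factory():
    return make_stream


@pytest.fixture(scope="session")
def tester_labeled():
    """A simulated 4-day tester recording with ground-truth labels."""
    stream, diary = lw.simulate_recording(lw.SimulationConfig(seed=7, days=4))
    return lw.label_stream(stream, diary)


@pytest.fixture(scope="session")
def fitted_model(tester_labeled):
    train, _ = lw.split_train_validate(tester_labeled, lw.SplitPlan(0.8, seed=2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lw.fit(lw.derive_features(train.stream), train.labels)
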