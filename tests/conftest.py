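from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from epicollar import AccelTrace, SimulationConfig

T0 = datetime(2016, 1, 1, tzinfo=timezone.utc)


def at(seconds: float) -> datetime:
    """Absolute time ``seconds`` after the reference start."""
    return T0 + timedelta(seconds=seconds)


def iv(t0_s: float, t1_s: float):
    return (at(t0_s), at(t1_s))


def make_trace(samples, fs=100.0, start=T0, wear_mask=None) -> AccelTrace:
    return AccelTrace(start, fs, np.asarray(samples, dtype=np.float32),
                      wear_mask=wear_mask or [])


def static_trace(duration_s=60.0, fs=100.0, g_vec=(0.0, 0.0, -1.0)) -> AccelTrace:
    n = int(round(duration_s * fs))
    samples = np.tile(np.asarray(g_vec, dtype=np.float32), (n, 1))
    return make_trace(samples, fs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_cfg():
    """A seconds-scale study config: high seizure rate, no charging gaps."""
    return SimulationConfig(
        seed=7,
        duration_days=0.02,  # ~29 min per phase
        seizure_rate_per_day=120.0,
        seizure_duration_s=(30.0, 60.0),
        clonic_amp_g=(2.5, 3.5),
        gap_schedule=(0.0, 0.0),
    )
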