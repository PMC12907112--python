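import numpy as np
import pytest

import tgdecode as tg
from tgdecode.epochs import (EpochsSet, baseline_correct,
                             common_average_reference, downsample_pairs)


@pytest.fixture(scope="session")
def montage():
    return tg.default_montage()


@pytest.fixture(scope="session")
def network_map():
    return tg.NetworkMap()


def make_epochs(n_trials=4, n_channels=3, sfreq=100.0, t_start=-200.0,
                n_times=41, labels=None, data=None, seed=0,
                channels=None) -> EpochsSet:
    """Small synthetic EpochsSet for unit tests."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.normal(0.0, 5.0, (n_trials, n_channels, n_times))
    else:
        data = np.asarray(data, dtype=float)
        n_trials, n_channels, n_times = data.shape
    times = t_start + (1000.0 / sfreq) * np.arange(n_times)
    if labels is None:
        labels = ["a"] * (n_trials // 2) + ["b"] * (n_trials - n_trials // 2)
    channels = channels or tuple(f"ch{i}" for i in range(n_channels))
    return EpochsSet(data=data, times=times, sfreq=sfreq, channels=channels,
                     labels=np.asarray(labels, dtype=object))


def preprocess(e: EpochsSet) -> EpochsSet:
    return downsample_pairs(common_average_reference(baseline_correct(e)))


def condition_epochs(e: EpochsSet, cond: str) -> EpochsSet:
    d = e.select(cond)
    return EpochsSet(data=d, times=e.times, sfreq=e.sfreq,
                     channels=e.channels,
                     labels=np.full(len(d), cond, dtype=object),
                     subject=e.subject)
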