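import numpy as np
import pytest

from seiznet import EventTrain


@pytest.fixture
def regular_train():
    """40 events every 200 samples in a 10000-sample series."""
    return EventTrain("a", np.arange(1, 41) * 200, 10000)


@pytest.fixture
def lagged_train(regular_train):
    """The regular train shifted by +30 samples (a perfect follower)."""
    return EventTrain("b", regular_train.times + 30, 10000)


def make_train(times, length=10000, channel="x"):
    return EventTrain(channel, np.asarray(times, dtype=np.int64), length)
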