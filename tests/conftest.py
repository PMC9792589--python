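import numpy as np
import pytest

from orgephys.data import ChannelInfo, Recording, Region, StimulusProtocol
from orgephys.synth import default_grid_channels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_channels():
    return default_grid_channels()


@pytest.fixture
def small_recording(rng, grid_channels):
    """1 s, 16 channels at 2 kHz with a stimulus protocol."""
    fs = 2000.0
    data = rng.standard_normal((16, int(fs))) * 5.0
    stim = StimulusProtocol(onsets_s=np.array([0.3]), pulse_width_s=0.1,
                            pulse_rate_hz=2.0, train_duration_s=0.5)
    return Recording(data=data, fs_hz=fs, channels=grid_channels, stimulus=stim,
                     state="awake", provenance="unit-test fixture")


def make_single_channel(x, fs):
    """Wrap a 1-D signal as a one-channel Recording."""
    ch = [ChannelInfo(channel_id=0, row=0, col=0, region=Region.CORTEX)]
    return Recording(data=np.asarray(x)[None, :], fs_hz=fs, channels=ch)
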