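import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from laminar_ephys.recording import (ChannelGeometry, LaminarLFP, SpikeTable,
                                     TrialTable)
import pandas as pd


@pytest.fixture
def tiny_geometry():
    return ChannelGeometry(channel_index=[0, 1, 2, 3],
                           depth_um=[0.0, 20.0, 20.0, 40.0],
                           lateral_um=[0.0, -8.0, 8.0, 0.0],
                           included=[True, True, True, True])


@pytest.fixture
def tiny_session(tiny_geometry):
    """Four channels, 2 s at 1 kHz, two trials, two clusters."""
    rng = np.random.default_rng(42)
    mv_per_bit = 0.00195
    values = np.round(rng.standard_normal((4, 2000)) * 50) * mv_per_bit
    lfp = LaminarLFP(values=values, sampling_rate_hz=1000.0,
                     depth_um=tiny_geometry.depth_um)
    trials = TrialTable(pd.DataFrame({
        "trial_id": [0, 1], "modality": ["tactile", "visual"],
        "onset_s": [0.5, 1.2], "n_stimuli": [2, 1],
        "stim_param": ["air_puff", "grating"]}))
    spikes = SpikeTable(pd.DataFrame({
        "cluster_id": [0, 0, 1], "spike_time_s": [0.1, 0.9, 0.4],
        "cluster_depth_um": [20.0, 20.0, 700.0]}))
    return tiny_geometry, lfp, trials, spikes
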