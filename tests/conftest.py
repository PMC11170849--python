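"""Shared fixtures: synthetic sessions reused across test modules.

Session-scoped so the expensive full-montage sessions are generated once.
"""

import numpy as np
import pytest

from neurogait import (EpochedSession, KneeAngleTraces, generate_session,
                       low_noise_config, reduced_montage_config)
from neurogait.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_session():
    """Reduced 9-channel, 40-trial session under default conditions."""
    return generate_session(reduced_montage_config(seed=11))


@pytest.fixture(scope="session")
def low_noise_session():
    """Full-montage session under the landmark-recovery validation conditions."""
    return generate_session(low_noise_config(seed=1))


@pytest.fixture(scope="session")
def null_session():
    """Full-montage session with no class-dependent structure anywhere."""
    cfg = SimulationConfig(seed=9, discrim_strength=0.0,
                           pfcc_hemi_r_offset=0.0, mrcp_hemi_extra_uv=0.0)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def discrim_session():
    """Full-montage session whose only class signal is the premovement burst."""
    cfg = SimulationConfig(seed=9, pfcc_hemi_r_offset=0.0,
                           mrcp_hemi_extra_uv=0.0, onset_jitter_sd_s=0.01)
    return generate_session(cfg)


def make_noise_session(n_trials=20, n_channels=4, fs=500.0, seconds=10.0,
                       seed=0, labels=None, names=None):
    """Plain white-noise session for unit tests that need full control."""
    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    eeg = rng.standard_normal((n_trials, n_channels, n))
    if names is None:
        base = ["Cz", "C3", "C4", "P3", "FC4", "Pz", "P4", "FCz"]
        names = tuple(base[:n_channels])
    if labels is None:
        labels = np.array(["left", "right"] * (n_trials // 2))
    return EpochedSession(eeg, names, fs, labels)
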