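"""Shared fixtures: small synthetic recordings and head geometry."""

import numpy as np
import pytest

from megevoke.core_io import ChannelInfo, ChannelKind, Recording
from megevoke.simulate import SubjectSpec, simulate_subject, make_head_geometry


@pytest.fixture(scope="session")
def small_spec():
    return SubjectSpec(n_runs=1, n_trials=12, sfreq=600.0, n_meg_mag=20,
                       n_meg_grad=10, n_eeg=10, cortex_subdiv=1)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    """One simulated subject (one run) reused across read-only tests."""
    runs, truth = simulate_subject(small_spec, seed=11)
    return runs, truth


@pytest.fixture(scope="session")
def head():
    scalp, cortex, sphere = make_head_geometry(1)
    return scalp, cortex, sphere


def make_recording(data, sfreq=600.0, kinds=None, first_sample_time=0.0):
    """Minimal recording around a plain data matrix."""
    n_ch = data.shape[0]
    kinds = kinds or [ChannelKind.EEG] * n_ch
    rng = np.random.default_rng(0)
    channels = []
    for i, k in enumerate(kinds):
        pos = rng.normal(size=3)
        pos = 0.09 * pos / np.linalg.norm(pos)
        orient = pos / np.linalg.norm(pos) if k in (ChannelKind.MEG_MAG,
                                                    ChannelKind.MEG_GRAD) else None
        channels.append(ChannelInfo(f"CH{i:03d}", k, "V", pos, orient))
    return Recording(channels, np.asarray(data, float), sfreq, first_sample_time)
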