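import numpy as np
import pytest

from scdecode import (
    SessionConfig,
    WindowSpec,
    extract_windows,
    select_functional_channels,
    simulate_session,
)

SESSION_SEED = 1


@pytest.fixture(scope="session")
def default_session():
    """Full-size synthetic session (15 channels, 100 trials/target)."""
    return simulate_session(SessionConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def default_channels(default_session):
    return select_functional_channels(default_session)


@pytest.fixture(scope="session")
def spike_tensor_baseline_visual(default_session, default_channels):
    """Target-aligned spike tensor spanning baseline through visual epochs."""
    spec = WindowSpec(span=(-400.0, 200.0))
    return extract_windows(default_session, default_channels, spec, "spike")


@pytest.fixture(scope="session")
def small_session():
    """Small session for fast unit tests (6 channels, 20 trials/target)."""
    cfg = SessionConfig(n_channels=6, trials_per_target=20, seed=7)
    return simulate_session(cfg)


def make_tensor(values, labels, ends, modality="spike", alignment="target_onset", length=100.0):
    from scdecode.features import FeatureTensor

    return FeatureTensor(
        values=np.asarray(values, dtype=float),
        labels=labels,
        window_end_times=ends,
        alignment=alignment,
        modality=modality,
        window_length=length,
    )
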