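import numpy as np
import pytest

from eegwcst import CohortConfig, default_positions
from eegwcst.validation import VALIDATION_CHANNELS


@pytest.fixture(scope="session")
def channels():
    return VALIDATION_CHANNELS


@pytest.fixture(scope="session")
def positions(channels):
    return default_positions(channels)


@pytest.fixture(scope="session")
def clean_config(channels):
    """Small artifact-free cohort at a reduced sampling rate."""
    return CohortConfig(
        n_subjects=6,
        seed=42,
        fs=256.0,
        task_duration=60.0,
        channels=channels,
        n_blink_epochs=0,
        n_amplitude_epochs=0,
    )


@pytest.fixture(scope="session")
def clean_subject(clean_config, positions):
    """One synthesized subject (truth + raw task recording)."""
    from eegwcst.synthdata import draw_subject_truths, synthesize_eeg

    truth = draw_subject_truths(clean_config)[0]
    rec = synthesize_eeg(
        truth,
        clean_config.task_duration,
        clean_config.fs,
        clean_config.channels,
        positions,
        seed=7,
        config=clean_config,
    )
    return truth, rec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
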