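import numpy as np
import pytest

from ftss import (
    SynthesisConfig,
    preprocess,
    preprocessed_truth,
    segment,
    simulate_ftss_recording,
)


@pytest.fixture(scope="session")
def torso_trial():
    """Clean simulated torso trial: (raw, preprocessed, truth-in-trimmed-frame)."""
    raw, truth = simulate_ftss_recording(SynthesisConfig(seed=1), "torso")
    rec = preprocess(raw)
    return raw, rec, preprocessed_truth(raw, truth)


@pytest.fixture(scope="session")
def thigh_trial():
    raw, truth = simulate_ftss_recording(SynthesisConfig(seed=2), "thigh")
    rec = preprocess(raw)
    return raw, rec, preprocessed_truth(raw, truth)


@pytest.fixture(scope="session")
def torso_segmented(torso_trial):
    _, rec, _ = torso_trial
    return rec, segment(rec)


@pytest.fixture(scope="session")
def thigh_segmented(thigh_trial):
    _, rec, _ = thigh_trial
    return rec, segment(rec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
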