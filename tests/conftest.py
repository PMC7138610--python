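import numpy as np
import pytest

from gainsep import (
    ConditionLabel,
    anesthetized_ground_truth,
    default_contrast_protocol,
    default_train_protocol,
)

V = ConditionLabel(stimulus="V", photostim="off")
V_PH = ConditionLabel(stimulus="V", photostim="on")
S = ConditionLabel(stimulus="S", photostim="off")
S_PH = ConditionLabel(stimulus="S", photostim="on")


@pytest.fixture(scope="session")
def train_proto():
    """Paper-timing trial-train protocol at a reduced 20 Hz sampling rate."""
    return default_train_protocol(frame_rate=20.0)


@pytest.fixture(scope="session")
def train_proto_100():
    """Full-rate (100 Hz) trial-train protocol."""
    return default_train_protocol()


@pytest.fixture(scope="session")
def contrast_proto():
    """Contrast-series protocol at 25 Hz."""
    return default_contrast_protocol(frame_rate=25.0)


@pytest.fixture
def clean_gt():
    """Small noiseless ground truth: no artifacts, no noise, no late rise."""
    return anesthetized_ground_truth(
        seed=7,
        image_shape=(24, 24),
        noise_std=0.0,
        late_rise=(4.0, 0.0),
        spont_process=(0.0, 1.0),
    )


@pytest.fixture
def noisy_gt():
    return anesthetized_ground_truth(
        seed=11,
        image_shape=(24, 24),
        noise_std=1.0,
        heartbeat_amp=0.5,
        respiration_amp=0.5,
    )
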