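"""Shared fixtures: small simulated sequences reused across test modules."""

import numpy as np
import pytest

from ocupulse import segmentation, synthetic


def small_params(**overrides) -> synthetic.BScanSimParams:
    """Scaled-down acquisition: 10 um peak-to-valley pulse at 1.2 Hz."""
    defaults = dict(
        n_frames=100,
        duration_s=4.0,
        width_px=200,
        depth_px=192,
        pulse_amplitude_um=5.0,
        heart_rate_hz=1.2,
        pause_prob=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return synthetic.BScanSimParams(**defaults)


@pytest.fixture(scope="session")
def clean_sequence():
    """Noise-free, drift-free 100-frame sequence with ground truth."""
    return synthetic.simulate_bscan_sequence(
        small_params(speckle_sigma=0.0, drift_amplitude_um=0.0)
    )


@pytest.fixture(scope="session")
def noisy_sequence():
    """Default-speckle sequence (with drift) and its ground truth."""
    return synthetic.simulate_bscan_sequence(small_params())


@pytest.fixture(scope="session")
def clean_segmentation(clean_sequence):
    seq, truth = clean_sequence
    wf, seg = segmentation.segment_sequence(seq)
    return seq, truth, wf, seg


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_sequence):
    seq, truth = noisy_sequence
    wf, seg = segmentation.segment_sequence(seq)
    return seq, truth, wf, seg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
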