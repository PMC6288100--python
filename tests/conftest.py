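import numpy as np
import pytest

from shearfret import GroundTruth, RatioMap, generate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def noisefree_truth():
    """Quiet generator setup whose flow-axis span (79 px) shares no factor
    with the 50 bins, so no pixel lands exactly on an interior bin edge."""
    return GroundTruth(
        center=(64.0, 64.5),
        semi_axes=(40.0, 28.0),
        shot_noise=False,
        read_noise_sd=0.0,
        decay_amplitude=0.25,
        gradient_slope=0.4,
        stimulus_onset_frame=5,
    )


@pytest.fixture
def noisefree_stack(noisefree_truth):
    return generate_stack(noisefree_truth, n_frames=15)


def random_ratio_map(rng, shape=(32, 32), density=0.4, dyadic=True):
    """Random masked ratio image; dyadic values keep float sums exact."""
    valid = rng.random(shape) < density
    if not valid.any():
        valid[shape[0] // 2, shape[1] // 2] = True
    if dyadic:
        vals = rng.integers(1, 64, shape) / 8.0
    else:
        vals = rng.uniform(0.1, 3.0, shape)
    ratio = np.where(valid, vals, 0.0)
    return RatioMap(ratio=ratio, valid=valid)
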