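import numpy as np
import pytest

from waspeye import GroundTruthRF, StimulusSpec


@pytest.fixture
def stim() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture
def quiet_rf() -> GroundTruthRF:
    """Noiseless, zero-latency RF centred in the ROI."""
    return GroundTruthRF(centre_x=0.0, centre_y=0.0, sigma_h=0.55,
                         sigma_v=0.55, amplitude=3.0, latency=0.0,
                         noise_sd=0.0, seed=0)


def grid_moments(values: np.ndarray, axis_coords: np.ndarray, axis: int):
    """Mean and variance of a nonnegative grid profile along one axis.

    Independent moment oracle used to check convolution identities: for a
    discrete convolution of nonnegative profiles, means and variances add
    exactly.
    """
    w = values.sum(axis=1 - axis)
    tot = w.sum()
    mean = (w * axis_coords).sum() / tot
    var = (w * (axis_coords - mean) ** 2).sum() / tot
    return mean, var
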