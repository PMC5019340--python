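import numpy as np
import pytest

from desilasso.io import MassAxis
from desilasso.synthetic import ClassProfile, NoiseModel, Peak

SEED = 20130227


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def small_axis():
    """A 60-channel axis over m/z 100-110 for cheap spectral tests."""
    return MassAxis(np.linspace(100.0, 110.0, 60))


@pytest.fixture
def small_profiles():
    """Three toy class profiles living on the small axis."""
    return {
        "cancer": ClassProfile("cancer", (Peak(102.0, 1.0, 0.2), Peak(107.0, 0.6, 0.2))),
        "glands": ClassProfile("glands", (Peak(104.0, 1.0, 0.2), Peak(108.5, 0.5, 0.2))),
        "stroma": ClassProfile(
            "stroma", (Peak(104.0, 0.8, 0.2), Peak(101.0, 0.4, 0.2)),
            total_abundance_scale=0.4,
        ),
    }


@pytest.fixture
def noise_off():
    return NoiseModel.off()
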