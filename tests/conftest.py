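import numpy as np
import pytest

from galoris import BandFeatureMatrix, SyntheticSpec, generate_band_features

INFORMATIVE = ("Delta_AF3", "Alpha_F3", "Beta_O2")


@pytest.fixture(scope="session")
def small_dataset():
    """500-sample two-state draw with three informative columns of 45."""
    spec = SyntheticSpec(
        n_samples=500, effect_size=2.0, informative_columns=INFORMATIVE, seed=11
    )
    matrix, labels, mask = generate_band_features(spec)
    return matrix, labels, mask, spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
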