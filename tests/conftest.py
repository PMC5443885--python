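import numpy as np
import pytest

from serialbsi import ImagePair, NoiseSpec, PhantomSpec, make_phantom_pair
from serialbsi.phantom import add_acquisition_noise


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom pair with masks and voxel-exact truth."""
    return make_phantom_pair(PhantomSpec())


def noisy_pair(pair: ImagePair, seed: int, snr: float = 25.0,
               model: str = "rician") -> ImagePair:
    """Independent acquisition noise on both timepoints of a pair."""
    n1 = add_acquisition_noise(
        pair.baseline, NoiseSpec(snr_center=snr, noise_model=model, seed=2 * seed))
    n2 = add_acquisition_noise(
        pair.followup, NoiseSpec(snr_center=snr, noise_model=model,
                                 seed=2 * seed + 1))
    return ImagePair(n1, n2, pair.voxel_volume)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
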