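import numpy as np
import pytest

from replicadetect import PhantomParams, SegMask, Volume, generate_study


def random_volume(seed: int, shape=(8, 8, 4), spacing=(1.0, 1.0, 1.0)) -> Volume:
    rng = np.random.default_rng(seed)
    return Volume(rng.random(shape), spacing=spacing, id=f"v{seed}")


def random_mask(seed: int, shape=(8, 8, 4), n_labels=1, p=0.3, spacing=(1.0, 1.0, 1.0)) -> SegMask:
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int64)
    for lab in range(1, n_labels + 1):
        labels[(rng.random(shape) < p) & (labels == 0)] = lab
    return SegMask(labels, spacing=spacing, id=f"m{seed}")


@pytest.fixture
def vol_pair():
    return random_volume(1), random_volume(2)


@pytest.fixture(scope="session")
def tiny_params():
    return PhantomParams(shape=(16, 16, 8), lesion_count=(1, 2), lesion_radius=(1.5, 3.0))


@pytest.fixture(scope="session")
def tiny_study(tiny_params):
    """Small planted study: 10 training, 8 synthetic, half exact-copy replicas."""
    return generate_study(
        n_train=10, n_synth=8, replica_fraction=0.5, seed=11, params=tiny_params
    )
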