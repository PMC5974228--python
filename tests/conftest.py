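import logging

import numpy as np
import pytest

import multiseed as ms

logging.getLogger("multiseed").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_atlas():
    """10 contiguous regions in a 16x16x8 grid."""
    return ms.make_toy_atlas(10, shape=(16, 16, 8), min_region_voxels=8, seed=42)


@pytest.fixture(scope="session")
def two_community_spec(toy_atlas):
    assignment = {int(r): (int(r) - 1) % 2 + 1 for r in toy_atlas.region_ids}
    return ms.CommunitySpec(assignment=assignment, signal_gain=1.0, noise_sd=1.0,
                            region_noise_sd=0.3)


@pytest.fixture(scope="session")
def toy_series(toy_atlas, two_community_spec):
    return ms.simulate_bold(toy_atlas, two_community_spec, n_volumes=150, tr=2.0, seed=7)


@pytest.fixture(scope="session")
def toy_seeds(toy_atlas):
    return ms.place_all_seeds(toy_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
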