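import numpy as np
import pytest

from overlapnet.atlas import AtlasRegion, SocialBrainAtlas, load_atlas
from overlapnet.roi import zscore_apply, zscore_fit
from overlapnet.synthetic import SyntheticSpec, simulate_dataset, simulate_volumes


@pytest.fixture(scope="session")
def default_atlas():
    return load_atlas("default")


@pytest.fixture()
def toy_atlas():
    """3-region atlas inside a small phantom grid (identity affine)."""
    regions = (
        AtlasRegion("a", "left", (5.0, 5.0, 5.0), "visual_sensory"),
        AtlasRegion("b", "right", (14.0, 5.0, 5.0), "visual_sensory"),
        AtlasRegion("c", "midline", (10.0, 14.0, 14.0), "limbic"),
    )
    return SocialBrainAtlas(regions=regions, source="toy")


@pytest.fixture(scope="session")
def rank15_dataset():
    """Noise-free rank-15 volumes from orthonormal planted loadings."""
    spec = SyntheticSpec(n_participants=700, n_factors=15, noise_sd=0.0,
                         orthonormal=True, seed=7)
    return simulate_volumes(spec)


@pytest.fixture(scope="session")
def rank15_zscored(rank15_dataset):
    vm = rank15_dataset.volumes
    return zscore_apply(vm, zscore_fit(vm))


@pytest.fixture(scope="session")
def small_traits_dataset():
    """Moderate-noise dataset with covariates for prediction tests."""
    spec = SyntheticSpec(n_participants=1200, n_factors=6, n_regions=18,
                         support_size=4, noise_sd=0.3, trait_effect=3.0,
                         n_traits=3, seed=21)
    return simulate_dataset(spec)
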