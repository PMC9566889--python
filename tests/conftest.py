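import numpy as np
import pytest
from hypothesis import settings

import petstratify as ps

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config():
    """Small-grid planted-effect study conditions used across module tests."""
    return ps.SimulationConfig(
        grid_shape=(12, 14, 12),
        voxel_size_mm=(4.0, 4.0, 4.0),
        n_per_class=(8, 8),
        effect_regions=[
            ps.EffectRegion(center=(4, 5, 7), radius_voxels=2, sign="hypo", amplitude=0.3),
            ps.EffectRegion(center=(7, 9, 5), radius_voxels=2, sign="hyper", amplitude=0.3),
        ],
        noise_sd=0.05,
        global_scale_sd=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return ps.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return ps.vectorize(tiny_cohort, fwhm_mm=8.0, target=50.0)


@pytest.fixture(scope="session")
def tiny_model(tiny_features, tiny_cohort):
    return ps.train_svm(tiny_features, ps.SvmParams(), mask=tiny_cohort.mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
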