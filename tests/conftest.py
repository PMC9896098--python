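import numpy as np
import pytest

import fcfwer as f


@pytest.fixture(scope="session")
def cohort16():
    """16-subject null cohort of smooth unit fields on a 64x64 brain mask."""
    cfg = f.SyntheticConfig(grid_shape=(64, 64), n_subjects=16, fwhm_true=10.0,
                            rng_seed=11)
    mask = f.make_brain_mask(cfg)
    maps = f.simulate_null_subject_maps(cfg, 1)[:, 0]
    return cfg, mask, maps


@pytest.fixture(scope="session")
def fields128():
    """Independent smooth Gaussian fields (kernel FWHM 10) on a 128x128 mask."""
    cfg = f.SyntheticConfig(grid_shape=(128, 128), n_subjects=400,
                            fwhm_true=10.0, rng_seed=21)
    mask = f.make_brain_mask(cfg)
    maps = f.simulate_null_subject_maps(cfg, 1)[:, 0]
    return cfg, mask, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
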