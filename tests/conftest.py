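import numpy as np
import pytest

import marshphen as mp


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless scene: no tide, no cloud, zero NDVI/SAR noise."""
    config = mp.SceneConfig(grid_shape=(4, 4), cloud_prob=0.0, seed=11)
    tide = mp.TideModel(shore_prob=0.0, inland_prob=0.0, shore_cols=0)
    pheno = mp.default_pheno_profiles(noise_sd=0.0)
    sar = mp.default_sar_profiles(noise_sd_db=0.0)
    labels, optical, sar_stack = mp.generate_scene(config, pheno, sar, tide)
    return {
        "config": config,
        "tide": tide,
        "pheno_profiles": pheno,
        "sar_profiles": sar,
        "labels": labels,
        "optical": optical,
        "sar": sar_stack,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
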