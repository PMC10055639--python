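import numpy as np
import pytest
from hypothesis import settings

from ratfc.synth import SyntheticConfig, generate_dataset, simulate_cohort_matrices

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def latent_cohort():
    """Default-condition cohort drawn at the latent Fisher-z level:
    10 rats/sex, 2 scans/rat, 64 regions, planted sex effects."""
    cfg = SyntheticConfig(n_rats_per_sex=10, scans_per_rat=2, seed=11)
    mats, sex, rat, estrus = simulate_cohort_matrices(cfg)
    return cfg, mats, sex, rat, estrus


@pytest.fixture(scope="session")
def voxel_scan():
    """One full voxel-level synthetic scan (240 volumes) with motion spikes."""
    cfg = SyntheticConfig(
        n_rats_per_sex=1,
        scans_per_rat=1,
        n_volumes=240,
        motion_spike_prob=0.02,
        seed=5,
    )
    ds = generate_dataset(cfg)
    return cfg, ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
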