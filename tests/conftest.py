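import numpy as np
import pytest

from poolscan.pileup_io import PoolSpec, SiteFilterConfig
from poolscan.simdata import SimConfig, default_sweeps, simulate
from poolscan.sweepcall import ContrastConfig

STUDY_POOLS = [
    PoolSpec("NSCT", 18),
    PoolSpec("NSD", 25),
    PoolSpec("SB", 22),
]


@pytest.fixture
def pools():
    return list(STUDY_POOLS)


@pytest.fixture
def default_filters():
    return SiteFilterConfig()


@pytest.fixture
def contrast():
    return ContrastConfig(focal_pair=("NSCT", "NSD"), control_pair=("NSCT", "SB"))


def small_sim_config(seed: int = 42, **overrides) -> SimConfig:
    """A 1 Mb / 8,000-site dataset with 5 planted sweeps: fast but complete."""
    kwargs = dict(
        n_sites=8000,
        chrom_length_bp=1_000_000,
        n_filler=300,
        sweep_loci=default_sweeps(1_000_000, n_sweeps=5),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_sim_config()
    mat, truth = simulate(cfg)
    return cfg, mat, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
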