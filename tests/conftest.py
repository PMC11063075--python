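"""Shared fixtures: small synthetic studies generated once per session."""

import numpy as np
import pytest

import exertrait
from exertrait.config import PlantedEffects, SimConfig


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_tissues=3,
        n_traits=4,
        n_categories=2,
        n_genes=400,
        n_samples_human=60,
        n_snps=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_de(small_config):
    return exertrait.generate_de_study(small_config)


@pytest.fixture(scope="session")
def small_twas(small_config, small_de):
    return exertrait.generate_twas(small_config, small_de)


@pytest.fixture(scope="session")
def small_degs(small_de):
    return exertrait.deg_sets(small_de)


@pytest.fixture(scope="session")
def enriched_setup():
    """Mid-sized study with a strong planted overall enrichment."""
    cfg = SimConfig(
        n_tissues=5,
        n_traits=8,
        n_categories=4,
        n_genes=1500,
        n_samples_human=60,
        n_snps=120,
        de_fraction=0.15,
        seed=5,
        planted_effects=PlantedEffects(alpha=1.0),
    )
    de = exertrait.generate_de_study(cfg)
    twas = exertrait.generate_twas(cfg, de)
    degs = exertrait.deg_sets(de)
    return cfg, de, twas, degs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
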