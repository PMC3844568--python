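import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stoichproteo.phylo import Phylogeny
from stoichproteo.simulate import (
    SimulationConfig,
    analytic_composition,
    load_tree,
    simulate_family_compositions,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_tree() -> Phylogeny:
    return load_tree(SimulationConfig())


@pytest.fixture(scope="session")
def star3() -> Phylogeny:
    return Phylogeny.from_string("(A:1,B:1,C:1);")


@pytest.fixture(scope="session")
def small_composition(default_tree):
    """Analytic composition table for a small multi-category family set."""
    cfg = SimulationConfig(seed=20130904, n_families=150)
    fams = simulate_family_compositions(cfg, default_tree,
                                        np.random.default_rng(cfg.seed))
    return analytic_composition(fams)
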