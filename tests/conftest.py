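import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mlqmmm.freeenergy import SamplerConfig
from mlqmmm.qmmm import EmbeddingScheme
from mlqmmm.synthetic import BoxSpec, generate_box, generate_solute


@pytest.fixture(scope="session")
def solute_system():
    """(reactant Structure, product Structure, SurrogateSolute), seed-fixed."""
    return generate_solute(seed=1)


@pytest.fixture(scope="session")
def small_box():
    """16 waters in a 7.9 Å cube (liquid density), for fast coupling tests."""
    return generate_box(BoxSpec(length=7.9, n_waters=16, seed=5))


@pytest.fixture(scope="session")
def centered_system(solute_system):
    """Solute centered in a 64-water box at liquid density."""
    reactant, product, solute = solute_system
    length = 12.4
    shift = length / 2.0 - reactant.coords.mean(axis=0)
    rc = reactant.coords + shift
    pc = product.coords + shift
    box = generate_box(BoxSpec(length=length, n_waters=64, seed=2), exclude=rc)
    return rc, pc, solute, box


@pytest.fixture
def scheme():
    return EmbeddingScheme(cutoff=15.0)


@pytest.fixture
def quick_sampler():
    """Short sampler settings for smoke-level statistical tests."""
    return SamplerConfig(n_equilibration=40, n_production=120, stride=4, seed=9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
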