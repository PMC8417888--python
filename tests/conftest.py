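import numpy as np
import pytest

from mfblup.pedigree import Pedigree
from mfblup.simdata import (SimConfig, TraitDef, TraitParams,
                            default_mating_plan, simulate)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_ped():
    """Two unrelated founders and their offspring."""
    return Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, 1]))


@pytest.fixture
def fullsib_ped():
    """Two founders, two full sibs, and a full-sib-mating offspring."""
    return Pedigree(np.array([-1, -1, 0, 0, 2]),
                    np.array([-1, -1, 1, 1, 3]))


def _small_config(**kw):
    defaults = dict(n_markers=300, n_base_per_breed=30,
                    mating_plan=default_mating_plan(scale=0.15),
                    genotype_founder_fraction=0.2, seed=202)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """Shared small composite population (~520 animals, 300 markers)."""
    return simulate(_small_config())


@pytest.fixture(scope="session")
def single_trait_sim():
    """Small population with one direct trait (polygenic only)."""
    tp = TraitParams(traits=[TraitDef("t", 0.3, 0.7, cg_scheme="fy")],
                     marker_fraction=0.0)
    return simulate(_small_config(trait_params=tp, seed=77))


@pytest.fixture
def small_config_factory():
    return _small_config
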