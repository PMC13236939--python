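"""Shared fixtures: coarse cohorts for invariant tests, nominal specimen for
contact tests.  Coarse meshes keep the suite fast; every property tested on
them is resolution-independent."""

import numpy as np
import pytest

from ratknee import GeneratorConfig, MaterialSet, generate_cohort
from ratknee.pipeline import nominal_specimen


def coarse_config(**kw) -> GeneratorConfig:
    base = dict(edge_length_bone=0.6, edge_length_patella=0.4, edge_length_articular=0.2)
    base.update(kw)
    return GeneratorConfig(**base)


def zero_variance_config(**kw) -> GeneratorConfig:
    zeros = {k: 0.0 for k in GeneratorConfig().between_animal_sd}
    return coarse_config(between_animal_sd=dict(zeros), within_animal_sd=dict(zeros), **kw)


@pytest.fixture(scope="session")
def materials() -> MaterialSet:
    return MaterialSet()


@pytest.fixture(scope="session")
def nominal():
    """Default-resolution nominal specimen (fine articular meshes)."""
    return nominal_specimen(GeneratorConfig())


@pytest.fixture(scope="session")
def coarse_cohort():
    return generate_cohort(coarse_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(coarse_config(seed=7, n_animals=2))
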