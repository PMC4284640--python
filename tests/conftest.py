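import numpy as np
import pytest

import neurosem as ns
from neurosem.models import prepare_model_frame
from neurosem.population import CohortConfig


@pytest.fixture(scope="session")
def pop():
    """Default calibrated population model."""
    return ns.build_population_model()


@pytest.fixture(scope="session")
def cohort200k(pop):
    return ns.generate_cohort(pop, 200000, seed=1)


@pytest.fixture(scope="session")
def frame200k(cohort200k):
    return prepare_model_frame(cohort200k)


@pytest.fixture(scope="session")
def cohort567(pop):
    return ns.generate_cohort(pop, 567, seed=42)


@pytest.fixture(scope="session")
def frame567(cohort567):
    return prepare_model_frame(cohort567)


@pytest.fixture(scope="session")
def fig7_config():
    """Population calibrated to the standardized mediation path values."""
    cfg = CohortConfig()
    cfg.age_to_neural = dict(cfg.age_to_neural)
    cfg.age_to_neural["gmv_ba10"] = -0.199
    cfg.neural_to_fluid = {"gmv_ba10": 0.156, "fa_fm": 0.131}
    cfg.neural_to_multitask = {"fa_atr": 0.155}
    cfg.age_to_fluid = -0.588
    cfg.age_to_multitask = -0.189
    return cfg


@pytest.fixture(scope="session")
def fig7_cohort200k(fig7_config):
    popm = ns.build_population_model(fig7_config)
    return prepare_model_frame(ns.generate_cohort(popm, 200000, seed=2))
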