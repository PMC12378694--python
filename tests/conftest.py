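import numpy as np
import pytest

from ccepflow.config import CohortConfig, EvokedModel, StimulationConfig
from ccepflow.geometry import generate_geometry
from ccepflow.signal_sim import attach_acquisition_meta


@pytest.fixture(scope="session")
def reduced_cfg() -> CohortConfig:
    return CohortConfig.reduced()


@pytest.fixture(scope="session")
def stim_cfg() -> StimulationConfig:
    return StimulationConfig()


@pytest.fixture(scope="session")
def evoked_model() -> EvokedModel:
    return EvokedModel()


@pytest.fixture(scope="session")
def small_geometry(reduced_cfg):
    """One deterministic reduced-geometry patient with acquisition metadata."""
    geom = generate_geometry(reduced_cfg, patient_seed=123, group="SF")
    return attach_acquisition_meta(geom, reduced_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250917)
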