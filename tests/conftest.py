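import numpy as np
import pytest

from msikit import clonality as clonality_mod
from msikit import msi as msi_mod
from msikit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Down-scaled conditions for fast unit tests."""
    return sd.SimulationConfig(seed=123, n_loci=8, n_reference=30, depth_per_locus=500)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return sd.generate_panel(small_config)


@pytest.fixture(scope="session")
def study_config() -> sd.SimulationConfig:
    """Default study conditions: 39 loci, 400 references, 5000x depth."""
    return sd.SimulationConfig(seed=2024)


@pytest.fixture(scope="session")
def study_panel(study_config):
    return sd.generate_panel(study_config)


@pytest.fixture(scope="session")
def study_references(study_config, study_panel):
    return sd.generate_reference_profiles(study_config, study_panel)


@pytest.fixture(scope="session")
def study_threshold(study_references, study_panel):
    return msi_mod.calibrate_threshold(study_references, study_panel)


@pytest.fixture(scope="session")
def study_envelope(study_references, study_panel):
    return clonality_mod.build_envelope(study_references, study_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(97531)
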