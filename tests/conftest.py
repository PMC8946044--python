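import numpy as np
import pytest

from minibeam.dosimetry import GEOMETRY_PRESETS, BeamGeometry
from minibeam.synthetic_tissue import DamageModel, TissueSpec, generate_section


@pytest.fixture(scope="session")
def small_spec() -> TissueSpec:
    """A short, sparse section: fast to render and segment."""
    return TissueSpec(
        section_length=300.0,
        thickness_band=40.0,
        mean_cells_per_section=40.0,
        cells_sd=4.0,
    )


@pytest.fixture(scope="session")
def full_spec() -> TissueSpec:
    return TissueSpec()


@pytest.fixture(scope="session")
def mech_model() -> DamageModel:
    return DamageModel(mode="mechanistic")


@pytest.fixture(scope="session")
def emp_model() -> DamageModel:
    return DamageModel(mode="empirical")


@pytest.fixture(scope="session")
def geom66() -> BeamGeometry:
    return GEOMETRY_PRESETS["66"]


@pytest.fixture(scope="session")
def geom920() -> BeamGeometry:
    return GEOMETRY_PRESETS["920"]


@pytest.fixture(scope="session")
def section_66_early(full_spec, geom66, mech_model):
    """A 66 µm mechanistic section at 0.5 h — the sharply clustered case."""
    return generate_section(full_spec, geom66, mech_model, 0.5, seed=11)


@pytest.fixture(scope="session")
def sham_section(full_spec, mech_model):
    return generate_section(full_spec, None, mech_model, 0.5, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
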