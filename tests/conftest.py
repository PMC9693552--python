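import numpy as np
import pytest

from saxsfibril import ExperimentGeometry, build_q_chi_map, default_geometry


@pytest.fixture(scope="session")
def small_geometry() -> ExperimentGeometry:
    """65x65 detector with the beam on an integer pixel, for exact checks."""
    return ExperimentGeometry(
        wavelength_nm=0.2,
        distance_mm=982.8,
        beam_center=(32.0, 32.0),
        pixel_size_mm=0.5,
        detector_shape=(65, 65),
    )


@pytest.fixture(scope="session")
def small_qmap(small_geometry):
    return build_q_chi_map(small_geometry)


@pytest.fixture(scope="session")
def desk_geometry():
    """The synthetic generator's default desk-scale beamline stand-in."""
    return default_geometry()


@pytest.fixture(scope="session")
def desk_qmap(desk_geometry):
    return build_q_chi_map(desk_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
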