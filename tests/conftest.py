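import numpy as np
import pytest

import qmristats as q


@pytest.fixture(scope="session")
def protocol() -> q.AcquisitionProtocol:
    """Full-size default protocol (7 TRs, 13 DWI frames)."""
    return q.AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_geometry() -> q.Geometry:
    return q.Geometry(matrix=(32, 32), n_slices=1)


@pytest.fixture(scope="session")
def small_spec(small_geometry) -> q.PhantomSpec:
    return q.default_study_spec(geometry=small_geometry)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(small_spec, small_geometry):
    """One simulated animal (truth + noisy series) on the small grid."""
    protocol = q.AcquisitionProtocol(geometry=small_geometry)
    animals = q.make_study(small_spec, seed=7)
    truth = animals[0]
    t1_series, dwi_series = q.simulate_animal(truth, protocol, sigma=20.0, seed=11)
    return small_spec, protocol, truth, t1_series, dwi_series
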