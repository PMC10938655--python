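import numpy as np
import pytest

import flowstarve as fs


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort: 4 patients x 30 breaths, fixed seed."""
    recordings, table = fs.simulate_recording(
        n_patients=4, breaths_per_patient=30, seed=123
    )
    return recordings, table


@pytest.fixture(scope="session")
def default_mech():
    return fs.PatientMechanics(resistance=10.0, compliance=50.0)


@pytest.fixture(scope="session")
def default_vent():
    return fs.VentilatorSettings(set_flow=30.0, Ti=1.0, peep=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240314)
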