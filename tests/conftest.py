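import numpy as np
import pytest

from calshock import (
    BiophysicalDerived,
    BiophysicalParameters,
    KineticParameters,
    StimulusProtocol,
    simulate,
)


@pytest.fixture(scope="session")
def kinetic():
    return KineticParameters()


@pytest.fixture(scope="session")
def biophys():
    return BiophysicalParameters()


@pytest.fixture(scope="session")
def derived(biophys):
    return BiophysicalDerived.from_parameters(biophys)


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def wt_trace(kinetic, biophys, protocol):
    """Wild-type shock simulation, calibrated to the default 215 nM baseline."""
    return simulate(kinetic, biophys, protocol)


@pytest.fixture(scope="session")
def random_states(kinetic, derived):
    """Random physically plausible state vectors for oracle comparisons."""
    rng = np.random.default_rng(42)
    n = 1000
    return np.column_stack(
        [
            derived.V_os0 * rng.uniform(0.8, 1.2, n),
            rng.uniform(0.0, 30_000.0, n),
            rng.uniform(0.0, kinetic.CaM_t, n),
            rng.uniform(0.0, kinetic.CaN_t, n),
        ]
    )
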