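import numpy as np
import pytest

from duofield.synthetic import SessionSpec, gen_dual_area_session
from duofield.traces import EventMatrix


@pytest.fixture(scope="session")
def coupled_session():
    """One default coupled dual-area session, shared across tests."""
    spec = SessionSpec(coupling=0.5, seed=7)
    areas, truth = gen_dual_area_session(spec)
    return spec, areas, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_events(rng):
    """A small dense event matrix at 10 Hz for unit tests."""
    values = rng.gamma(2.0, 0.5, size=(5, 200)) * (rng.random((5, 200)) < 0.2)
    return EventMatrix(values=values, frame_rate=10.0)
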