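"""Shared fixtures: compiled models and reference simulation runs.

Full multiscale runs are expensive, so each canonical run (sham / acute /
gradual at the default 24 h interval, and the 4 h phenotype-resolution runs)
is computed once per session and shared read-only across tests.
"""

import numpy as np
import pytest

from ischemix.multiscale import Protocol, simulate
from ischemix.signaling import default_cell_model
from ischemix.tissue import build_baseline


@pytest.fixture(scope="session")
def cell():
    return default_cell_model()


@pytest.fixture(scope="session")
def baseline():
    return build_baseline()


@pytest.fixture(scope="session")
def rest_state(cell):
    return cell.resting_state()


@pytest.fixture(scope="session")
def sham_run():
    return simulate(Protocol("sham"))


@pytest.fixture(scope="session")
def acute_run():
    return simulate(Protocol("acute"))


@pytest.fixture(scope="session")
def gradual_run():
    return simulate(Protocol("gradual"))


@pytest.fixture(scope="session")
def acute_run_4h():
    return simulate(Protocol("acute"), config={"interval_hours": 4})


@pytest.fixture(scope="session")
def gradual_run_4h():
    return simulate(Protocol("gradual"), config={"interval_hours": 4})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
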