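import logging

import pytest

from forceglide.pipeline import make_fixtures

logging.getLogger("forceglide").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """Deterministic small fixture bundle shared across the suite."""
    return make_fixtures("small", seed=0)


@pytest.fixture(scope="session")
def events_sim(bundle):
    return bundle["events_sim"]


@pytest.fixture(scope="session")
def mech_sim(bundle):
    return bundle["mech_sim"]


@pytest.fixture(scope="session")
def rendered(bundle):
    return bundle["render_sim"], bundle["motor_stack"], bundle["mt_stack"], bundle["truth_spots"]
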