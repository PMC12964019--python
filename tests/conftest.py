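import numpy as np
import pytest

from mhqpeldor import instrument as inst
from mhqpeldor import synthetic as syn


@pytest.fixture(scope="session")
def geometry():
    return inst.MhqGeometry()


@pytest.fixture(scope="session")
def flow():
    """Reference pump setting: 2 mL/min combined over two channels."""
    return inst.FlowSettings.from_total_ml_per_min(2.0)


@pytest.fixture(scope="session")
def fixture_spec():
    return syn.FixtureSpec(seed=1234)


@pytest.fixture(scope="session")
def reference_pair():
    """Noiseless apo/holo reference traces and their true distributions."""
    spec = syn.FixtureSpec(seed=1234, noise_sd=0.0)
    return syn.make_reference_pair(spec)
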