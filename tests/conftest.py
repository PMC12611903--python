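import numpy as np
import pytest

from avmseg.phantom import PhantomParams, generate_case


@pytest.fixture(scope="session")
def default_case():
    """One deterministic phantom case shared across read-only tests."""
    return generate_case(PhantomParams(seed=7), case_id="fixture_case")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
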