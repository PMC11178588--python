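import pytest

from acdose.chain import default_chain


@pytest.fixture(scope="session")
def chain():
    return default_chain()


@pytest.fixture(scope="session")
def small_scenario():
    """A two-patient cohort on a 64³ grid, shared across image-level tests."""
    from acdose.synth import default_scenario

    return default_scenario(seed=7, n_patients=2, grid_shape=(64, 64, 64))
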