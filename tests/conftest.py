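import pytest

from plaquekit import phantom


@pytest.fixture(scope="session")
def truth():
    """One default synthetic subject shared across read-only tests."""
    return phantom.make_phantom(seed=1)


@pytest.fixture(scope="session")
def t1w(truth):
    return phantom.render_t1w(truth, "standalone")


@pytest.fixture(scope="session")
def noiseless_series(truth):
    return phantom.render_dixon(truth, noise_sd=0.0, seed=1)
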