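import pytest

from lileychaos import load_fixture


@pytest.fixture(scope="session")
def standard_params():
    """Standard physiological parameter set, inputs at the reference point."""
    return load_fixture("standard")


@pytest.fixture(scope="session")
def demo_params():
    return load_fixture("demo")
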