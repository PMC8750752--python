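import pytest

from hcedecomp import default_generator_config, generate_panel


@pytest.fixture(scope="session")
def tiny_panel():
    """Small default-condition panel shared by cheap structural tests."""
    panel, truth = generate_panel(default_generator_config(scale=300, seed=7))
    return panel, truth


@pytest.fixture(scope="session")
def mid_panel():
    """Mid-sized panel for sampling-error-bounded statistical checks."""
    panel, truth = generate_panel(default_generator_config(scale=5000, seed=11))
    return panel, truth
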