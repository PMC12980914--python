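import pytest

from coatcall.panel import load_panel, panel_by_id
from coatcall.synthio import SynthConfig


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def idx(panel):
    return panel_by_id(panel)


@pytest.fixture
def clean_config():
    """Error-free sequencing, fixed seed."""
    return SynthConfig(base_error_rate=0.0, rng_seed=11)
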