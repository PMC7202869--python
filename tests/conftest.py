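import pytest

from hostshift import scenario


@pytest.fixture(scope="session")
def e2e():
    """One full run of the standard synthetic study (shared across tests).

    Simulates ~1M DNA reads at 60x over a 1-Mb focal scaffold with an
    8-copy 30-kb tandem unit, plus the RNA layer, and executes every
    inference stage.
    """
    return scenario.run_end_to_end(seed=1)
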