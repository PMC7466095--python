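import pytest

from introdissect.simdata import SimConfig, generate_parents, plant_introgression


@pytest.fixture(scope="session")
def default_line():
    """One planted introgression line under the default study conditions."""
    return plant_introgression(generate_parents(SimConfig(seed=1)))


@pytest.fixture(scope="session")
def noisy_line():
    """A line with expression dropout and spurious-variant noise."""
    cfg = SimConfig(seed=2, expression_dropout=0.2, variant_error_rate=1e-5)
    return plant_introgression(generate_parents(cfg))
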