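import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from midgemito.simulate import (
    SyntheticGenomeSpec,
    generate_biotype_panel,
    generate_mitogenome,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gmb1():
    """One GMB1 genome with ground truth (seed 1)."""
    return generate_mitogenome(SyntheticGenomeSpec(biotype="GMB1", seed=1))


@pytest.fixture(scope="session")
def panel():
    """The nine-genome biotype/species panel (seed 1)."""
    return generate_biotype_panel(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
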