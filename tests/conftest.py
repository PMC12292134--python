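import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mitocensus import load_reference_annotation
from mitocensus.synthetic import GeneratorConfig, generate_genome


@pytest.fixture(scope="session")
def reference():
    """The published E. machnata annotation table (sequence-less)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def synth():
    """One default synthetic genome + sidecar, shared across tests
    (read-only; regenerating is ~2 s)."""
    return generate_genome(GeneratorConfig(seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
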