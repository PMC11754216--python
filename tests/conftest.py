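import pytest

from vdjloci.rss import default_model
from vdjloci.simulate import LocusConfig, generate_locus


@pytest.fixture(scope="session")
def models():
    return default_model(12), default_model(23)


@pytest.fixture(scope="session")
def small_locus():
    """A skink-like synthetic locus shared across test modules."""
    cfg = LocusConfig(seed=3)
    locus, truth = generate_locus(cfg)
    return cfg, locus, truth
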