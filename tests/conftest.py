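import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_tree():
    from jtpeak.relevance import RelevanceTree

    return RelevanceTree.load_default()


@pytest.fixture(scope="session")
def canonical_beats():
    """Noiseless canonical beat + truth per morphology class."""
    from jtpeak import synthetic as syn

    out = {}
    for morph in syn.MORPHOLOGIES:
        spec = syn.canonical_spec(morph, seed=0)
        out[morph] = syn.generate_beat(spec)
    return out
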