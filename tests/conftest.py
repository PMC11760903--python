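import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """A small on-disk easy-fixture dataset shared across tests."""
    import algadet as ag

    out = tmp_path_factory.mktemp("dataset")
    ag.build_dataset(ag.SceneSpec.easy(128), 70, out, seed=1)
    return out
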