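import numpy as np
import pytest

from earcount.synthetic import SceneConfig, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A 400x400 easy-regime scene with 8 isolated ears and its truth."""
    cfg = SceneConfig(height=400, width=400, n_ears=8, adhesion=0.0, seed=42)
    return generate_scene(cfg)
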