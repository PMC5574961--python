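import numpy as np
import pytest

from sonokinetics.imaging import SceneConfig, apply_noise, generate_population_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 20-cell noiseless FCFM scene shared across imaging/tracking tests."""
    config = SceneConfig(n_cells=20)
    stack, truth = generate_population_stack(
        config, "usmb_fadu", 2.0,
        seed=np.random.default_rng(42), kinetics_rng=np.random.default_rng(43))
    return stack, truth


@pytest.fixture(scope="session")
def small_scene_noisy(small_scene):
    stack, truth = small_scene
    return apply_noise(stack, 20.0, seed=44, read_noise=0.5), truth
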