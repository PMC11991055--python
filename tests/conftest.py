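import numpy as np
import pytest

from lettucevision.synthdata import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def lesion_scene():
    """One moderate-nitrogen scene with truth, reused across modules."""
    spec = SceneSpec(lesion_class="N", lesion_fraction=0.15, seed=3)
    img, truth = generate_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, ramp-free moderate scene for denoising efficacy baselines."""
    spec = SceneSpec(
        lesion_class="N", lesion_fraction=0.15, noise_density=0.0,
        illum_gradient=0.0, seed=3,
    )
    img, truth = generate_scene(spec)
    return spec, img, truth
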