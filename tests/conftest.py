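import numpy as np
import pytest

from ldics import preprocess, synthetic
from ldics.synthetic import NoiseModel, SyntheticSpec


def small_spec(**overrides) -> SyntheticSpec:
    """A quick-to-render 256-pixel spec (25.6 µm frame, 20×6 µm hypha)."""
    kwargs = dict(image_size_pix=256, hypha_length_um=20.0, hypha_width_um=6.0,
                  n_droplets=10, seed=42)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


@pytest.fixture(scope="session")
def control_image_and_truth():
    """One full-size control-regime hypha image (1024 px, 12 droplets)."""
    spec = SyntheticSpec(seed=11)
    image, truth = synthetic.generate_hypha_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def control_mask(control_image_and_truth):
    _, image, _ = control_image_and_truth
    return preprocess.estimate_hypha_mask(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def clean_droplet_spec():
    """Noise-free, negligible-wall, zero-background spec: droplets only."""
    return small_spec(wall_peak=1e-9, background_level=0.0,
                      noise_model=NoiseModel.none())
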