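import numpy as np
import pytest

from jointatlas.phantom import PhantomSpec, make_template
from jointatlas.volumes import ImageVolume, LabelVolume

# A reduced-resolution geometry that holds the full anatomy: same physical
# extent as the default 96x96x64 grid at half resolution.
SMALL_SHAPE = (48, 48, 32)
SMALL_SPACING = (2.5, 2.5, 4.54)


@pytest.fixture(scope="session")
def clean_template():
    """Noise- and bias-free phantom template at reduced resolution."""
    return make_template(
        PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING, noise_sigma=0.0, bias_amplitude=0.0, seed=101)
    )


@pytest.fixture(scope="session")
def noisy_template():
    """Default-appearance phantom template at reduced resolution."""
    return make_template(PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING, seed=101))


@pytest.fixture(scope="session")
def full_template():
    """Noise-free template at the native 96x96x64 resolution."""
    return make_template(PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_image(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def toy_labels(data, spacing=(1.0, 1.0, 1.0), label_map=None):
    data = np.asarray(data)
    if label_map is None:
        label_map = {int(v): f"label_{int(v)}" for v in np.unique(data)}
        label_map.setdefault(0, "background")
    return LabelVolume(data, spacing, label_map=label_map)
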