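import numpy as np
import pytest

from histo25d.phantom import PhantomSpec, generate_phantom_core


@pytest.fixture(scope="session")
def nowarp_stack():
    """Default-size phantom with similarity misalignment only."""
    return generate_phantom_core(PhantomSpec(seed=7, warp_amplitude=0.0))


@pytest.fixture(scope="session")
def warped_stack():
    """Default phantom: similarity misalignment plus 6 px smooth warps."""
    return generate_phantom_core(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_stack():
    """Small fast phantom for segmentation / IO / CLI tests.

    Gland lumina are kept above the mask-closing scale so the hue masks
    have consistent topology across sections at this reduced canvas.
    """
    return generate_phantom_core(PhantomSpec(seed=3, canvas_size=192,
                                             n_sections=4, n_glands=3,
                                             gland_size_frac=(0.04, 0.065),
                                             translation_max_px=10.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
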