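import numpy as np
import pytest

from cosreg import (
    ADMMConfig,
    DeformationSpec,
    ImageGrid,
    PhantomSpec,
    SparsityConfig,
    Transform,
    extract_patch_pairs,
    generate_deformation,
    learn_operators,
    warp_image,
)
from cosreg.phantom import generate_scene

SMALL_SHAPE = (128, 128)
SMALL_SPACING = (1.2, 1.2)  # keeps the 150 mm body on a 128 px canvas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale phantom scene shared across tests (deterministic)."""
    return generate_scene(PhantomSpec(seed=11), SMALL_SHAPE, SMALL_SPACING)


@pytest.fixture(scope="session")
def small_pair(small_scene):
    """(float PA deformed, reference MR, gt field) on the small canvas."""
    fld = generate_deformation(
        DeformationSpec(max_displacement_px=4, smoothness_sigma_px=10, seed=21),
        SMALL_SHAPE,
    )
    fld.spacing = SMALL_SPACING
    pa_def = warp_image(small_scene.pa, Transform.from_field(fld))
    return small_scene.mr, pa_def, fld


@pytest.fixture(scope="session")
def small_operators(small_scene):
    """Quick operator pair learned on the aligned small-scene pair."""
    ens = extract_patch_pairs(small_scene.pa, small_scene.mr, 5, 600, seed=31)
    cfg = SparsityConfig(k_rows=40)
    op_pa, op_mr, state = learn_operators(ens, cfg, ADMMConfig(max_iter=20), seed=41)
    return op_pa, op_mr, state


@pytest.fixture()
def random_image(rng):
    return ImageGrid(rng.random((16, 16)))
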