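import numpy as np
import pytest

from periwater import (
    EffectProfile,
    PhantomSpec,
    build_phantom,
    make_gradient_table,
    make_truth_maps,
)


@pytest.fixture(scope="session")
def gtab64():
    """The study acquisition: 64 directions at b=1500 plus one b=0."""
    return make_gradient_table(64, 1500.0, 1, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom used where fit runtime matters."""
    return PhantomSpec(
        grid_shape=(21, 21, 21),
        lesion_center=(4, 10, 10),
        lesion_radii_mm=(3.0, 4.0, 4.0),
        ventricle_radii_mm=(3.0, 5.0, 4.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_masks(default_spec):
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def default_truth(default_spec, default_masks):
    return make_truth_maps(default_spec, EffectProfile(), 0, default_masks)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
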