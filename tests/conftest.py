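import numpy as np
import pytest

from sarcoshg import (
    CohortSpec,
    FiberSpec,
    SarcomereParams,
    parallel_fiber_layout,
    simulate_cohort,
    simulate_fiber_image,
)

#: Fetal control geometry used as the canonical test fiber.
FETAL_CONTROL = SarcomereParams(1.658, 0.772, 0.104)


@pytest.fixture(scope="session")
def fetal_params() -> SarcomereParams:
    return FETAL_CONTROL


@pytest.fixture(scope="session")
def horizontal_fiber_image():
    """Single noise-free horizontal fiber through the image center row."""
    fib = FiberSpec(
        params=FETAL_CONTROL,
        center_xy_px=(255.5, 128.0),
        orientation_deg=0.0,
        n_sarcomeres=12,
    )
    image, truth = simulate_fiber_image([fib], shape=(256, 512), noise=0.0, seed=0)
    return image, truth


@pytest.fixture(scope="session")
def oblique_image():
    """Five near-parallel 45-degree fibers at default noise, with truth."""
    rng = np.random.default_rng(7)
    layout = parallel_fiber_layout([FETAL_CONTROL] * 5, rng=rng)
    return simulate_fiber_image(layout, noise=1.0, seed=77, image_id="oblique")


@pytest.fixture(scope="session")
def oblique_image_clean():
    """Same geometry as ``oblique_image`` but noise-free."""
    rng = np.random.default_rng(7)
    layout = parallel_fiber_layout([FETAL_CONTROL] * 5, rng=rng)
    return simulate_fiber_image(layout, noise=0.0, seed=77, image_id="oblique0")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny paired fetal cohort (3+3 hearts, 1 image each) for pipeline tests."""
    spec = CohortSpec(age="fetal", n_hearts=3, images_per_heart=1, seed=21)
    return simulate_cohort(spec)
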