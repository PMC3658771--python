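import numpy as np
import pytest

from mpcontour import AlgoParams, run_multipass
from mpcontour.synthetic import PhantomSpec, make_nested_phantom


@pytest.fixture(scope="session")
def four_level_spec() -> PhantomSpec:
    """The reference study condition: 4 nested plateaus, 5% uniform noise."""
    return PhantomSpec(
        shape=(128, 128),
        levels=(40.0, 100.0, 160.0, 220.0),
        geometry="nested_squares",
        noise_frac=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def four_level_phantom(four_level_spec):
    return make_nested_phantom(four_level_spec)


@pytest.fixture(scope="session")
def four_level_result(four_level_phantom):
    image, _ = four_level_phantom
    return run_multipass(image, source_image_id="phantom-4level")


@pytest.fixture(scope="session")
def two_level_phantom():
    spec = PhantomSpec(
        shape=(64, 64),
        levels=(50.0, 200.0),
        geometry="nested_squares",
        noise_frac=0.0,
        seed=0,
    )
    return make_nested_phantom(spec)


@pytest.fixture(scope="session")
def two_level_result(two_level_phantom):
    image, _ = two_level_phantom
    return run_multipass(image, source_image_id="phantom-2level")


@pytest.fixture
def default_params() -> AlgoParams:
    return AlgoParams()


@pytest.fixture
def bright_square():
    """Noise-free 64x64 image: 20x20 square at 200 on a 50 background."""
    img = np.full((64, 64), 50.0)
    truth = np.zeros((64, 64), dtype=bool)
    truth[22:42, 22:42] = True
    img[truth] = 200.0
    return img, truth
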