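import numpy as np
import pytest

from tendonmri import (
    AdaptiveSegParams,
    ImageGeometry,
    LesionPhantomParams,
    generate_stack,
)


@pytest.fixture(scope="session")
def geometry() -> ImageGeometry:
    """Default acquisition geometry: 171 mm FOV, 256×256, 5 mm + 1 mm gap."""
    return ImageGeometry()


@pytest.fixture(scope="session")
def seg_params() -> AdaptiveSegParams:
    return AdaptiveSegParams()


@pytest.fixture(scope="session")
def lesion_stack(geometry):
    """A reproducible severity-0.8 phantom stack with ground truth."""
    params = LesionPhantomParams(severity=0.8, max_csa_mm2=30.0, seed=42)
    return generate_stack(params, geometry)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
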