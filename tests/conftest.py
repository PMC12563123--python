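import numpy as np
import pytest

from itwater import MixtureDensity, QuadratureSpec


@pytest.fixture
def unit_gaussian() -> MixtureDensity:
    """Isotropic sigma=1 Gaussian at the origin (position space)."""
    return MixtureDensity.from_parts(np.zeros((1, 3)), [1.0], [1.0])


@pytest.fixture
def fast_quad() -> QuadratureSpec:
    """Coarse-but-adequate quadrature for many-sample statistical tests."""
    return QuadratureSpec(base_points_per_axis=32, refinement_levels=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
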