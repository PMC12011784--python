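import numpy as np
import pytest

from histofuse.synthetic import ClassAppearance, generate_image


@pytest.fixture(scope="session")
def normal_appearance() -> ClassAppearance:
    return ClassAppearance(330.0, 0.30, 272.0, nucleus_density=10.0,
                           nucleus_radius_px=(4.0, 1.0), texture_grain=8.0)


@pytest.fixture(scope="session")
def small_image(normal_appearance) -> np.ndarray:
    """One deterministic 64x64 H&E-like image."""
    return generate_image(normal_appearance, (64, 64), 42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
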