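import numpy as np
import pytest

from cupdisc import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def centered_spec() -> PhantomSpec:
    """An 800x800 phantom with disc semi-axes (150, 120), cup (60, 50)."""
    return PhantomSpec(
        image_height=800,
        image_width=800,
        disc_center=(400.0, 400.0),
        disc_semi_axes=(150.0, 120.0),
        cup_center=(400.0, 400.0),
        cup_semi_axes=(60.0, 50.0),
        vessel_noise=True,
        seed=12345,
    )


@pytest.fixture(scope="session")
def centered_phantom(centered_spec):
    return generate_phantom(centered_spec)


@pytest.fixture(scope="session")
def refuge_scale_spec() -> PhantomSpec:
    """A REFUGE-sized 1634x1634 phantom: disc semi-axes (210, 200), cup
    (115, 110), true vCDR = 0.55.  At this scale the +/-1 px rasterization
    quantization is ~1% of the cup's vertical diameter."""
    return PhantomSpec(
        image_height=1634,
        image_width=1634,
        disc_center=(817.0, 817.0),
        disc_semi_axes=(210.0, 200.0),
        cup_center=(817.0, 817.0),
        cup_semi_axes=(115.0, 110.0),
        vessel_noise=True,
        seed=777,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240628)
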