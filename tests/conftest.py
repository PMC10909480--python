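import numpy as np
import pytest

from histomech import (
    LabelImage,
    MicrostructureSpec,
    generate_microstructure,
    NeoHookeanParams,
    HGOParams,
)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale anisotropic microstructure used across modules."""
    return MicrostructureSpec(
        width_px=128, height_px=128, pixel_size_um=4.0, n_acini=7,
        lumen_radius_mean_um=28.0, lumen_radius_sd_um=5.0,
        epithelium_thickness_um=12.0, elongation=3.0,
        preferred_angle_deg=25.0, angle_dispersion_deg=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_microstructure(small_spec):
    return generate_microstructure(small_spec)


@pytest.fixture(scope="session")
def all_stroma():
    return LabelImage(np.zeros((16, 16), dtype=np.uint8), 10.0)


@pytest.fixture(scope="session")
def nh_params():
    return NeoHookeanParams.from_poisson(10.0, 0.49)


@pytest.fixture(scope="session")
def hgo_params():
    return HGOParams(NeoHookeanParams.from_poisson(17.5, 0.49),
                     k1=155.0, k2=200.0, kappa=0.0)


def rng(seed=0):
    return np.random.default_rng(seed)


def stripe_image(angle_deg, n=128, period=16, px=1.0):
    """Stroma/epithelium stripes at a given axial orientation."""
    from histomech import STROMA, EPITHELIUM
    yy, xx = np.mgrid[:n, :n]
    t = np.deg2rad(angle_deg)
    d = -np.sin(t) * xx + np.cos(t) * yy  # distance along stripe normal
    labels = np.where((d % period) < period / 2, STROMA,
                      EPITHELIUM).astype(np.uint8)
    return LabelImage(labels, px)
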