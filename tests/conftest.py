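from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Polygon

from histoquant.images import BinaryMask, CalibratedImage, RegionOutline
from histoquant.synthetic import LatentFieldSpec, SceneSpec, StainModel, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_outline():
    return RegionOutline(
        MultiPolygon([Polygon([(0, 0), (50, 0), (50, 50), (0, 50)])]), label="square"
    )


@pytest.fixture
def full_region():
    def _make(shape, scale=1.0):
        return BinaryMask(np.ones(shape, dtype=bool), scale, source_label="full")

    return _make


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered scene with one structure and one nuclear channel."""
    spec = SceneSpec(
        width_um=900.0,
        height_um=900.0,
        scale_um_per_px=1.0,
        tubule_density_per_mm2=200.0,
        tubule_radius_um_range=(8.0, 14.0),
        nucleus_density_per_mm2=250.0,
        nucleus_radius_um_range=(2.5, 4.0),
        stain_models={
            "memb": StainModel("structure", fg_mean=200, fg_sd=8, bg_mean=10, bg_sd=4),
            "nuc": StainModel("nuclear", fg_mean=200, fg_sd=8, bg_mean=10, bg_sd=4),
        },
        latent_field=LatentFieldSpec(300.0, 0.0, 0.4),
        noise_sd=2.0,
        background_amplitude=10.0,
        seed=99,
    )
    images, truth = generate_scene(spec)
    return spec, {im.channel_label: im for im in images}, truth


def make_image(pixels, scale=1.0, **kw) -> CalibratedImage:
    return CalibratedImage(np.asarray(pixels, dtype=float), scale, **kw)
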