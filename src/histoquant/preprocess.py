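"""Whole-section intensity preprocessing: background subtraction, downsampling.

The background estimate is a grayscale morphological opening with a
ball-shaped (non-flat, Sternberg-style) structuring element: the envelope a
ball of the given radius traces when rolled under the intensity surface.
Fluorescence sections are dark-background, so no inversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .images import CalibratedImage

__all__ = ["BackgroundModel", "rolling_ball_subtract", "downsample", "ball_structuring_element"]

DEFAULT_BALL_RADIUS_PX = 50
# above this radius the envelope is computed on a block-min-shrunken image
# (ball radius scaled down accordingly) and enlarged by interpolation — the
# same large-radius strategy classic background subtractors use; below it the
# opening is exact
EXACT_RADIUS_LIMIT_PX = 16


@dataclass
class BackgroundModel:
    """The subtracted background surface; input = result + background exactly."""

    background: np.ndarray
    ball_radius_px: int


def ball_structuring_element(radius_px: int) -> np.ndarray:
    """Heights of a ball of given radius on the integer grid; NaN outside.

    Element value at offset ``s`` is ``sqrt(r^2 - |s|^2)`` for ``|s| <= r``.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    coords = np.arange(-radius_px, radius_px + 1)
    d2 = coords[:, None] ** 2 + coords[None, :] ** 2
    with np.errstate(invalid="ignore"):
        heights = np.sqrt(np.maximum(radius_px**2 - d2, -1.0))
    heights[d2 > radius_px**2] = np.nan
    return heights


def rolling_ball_subtract(
    image: CalibratedImage, radius_px: int = DEFAULT_BALL_RADIUS_PX
) -> tuple[CalibratedImage, BackgroundModel]:
    """Subtract the rolling-ball background envelope from an image.

    Returns the background-subtracted image (clipped at 0) and the model.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    h, w = image.shape
    if radius_px > h and radius_px > w:
        raise ValueError(
            f"ball radius {radius_px} exceeds both image dimensions {image.shape}"
        )
    pixels = image.pixels.astype(np.float64)
    background = _rolling_ball_background(pixels, radius_px)
    result = pixels - background
    out = CalibratedImage(
        result,
        image.scale_um_per_px,
        channel_label=image.channel_label,
        source_id=image.source_id,
    )
    return out, BackgroundModel(background=background, ball_radius_px=radius_px)


def _exact_ball_opening(pixels: np.ndarray, radius_px: int) -> np.ndarray:
    heights = ball_structuring_element(radius_px)
    footprint = ~np.isnan(heights)
    structure = np.where(footprint, heights, 0.0)
    return ndi.grey_opening(pixels, structure=structure, footprint=footprint, mode="nearest")


def _block_min(pixels: np.ndarray, factor: int) -> np.ndarray:
    h, w = pixels.shape
    ph = (-h) % factor
    pw = (-w) % factor
    padded = np.pad(pixels, ((0, ph), (0, pw)), mode="edge")
    return padded.reshape(
        padded.shape[0] // factor, factor, padded.shape[1] // factor, factor
    ).min(axis=(1, 3))


def _rolling_ball_background(pixels: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px <= EXACT_RADIUS_LIMIT_PX:
        background = _exact_ball_opening(pixels, radius_px)
    else:
        shrink = int(np.ceil(radius_px / 10))
        small = _block_min(pixels, shrink)
        small_radius = max(int(round(radius_px / shrink)), 1)
        small_bg = _exact_ball_opening(small, small_radius)
        background = resize(
            small_bg, pixels.shape, order=1, mode="edge", anti_aliasing=False
        )
    # opening is anti-extensive; guard against interpolation/round-off
    return np.minimum(background, pixels)


def downsample(image: CalibratedImage, factor: int) -> CalibratedImage:
    """Block-mean reduction by an integer factor; scale grows accordingly.

    Trailing rows/columns that do not fill a complete block are dropped.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    h, w = image.shape
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds image dimensions {image.shape}")
    if factor == 1:
        return CalibratedImage(
            image.pixels.copy(),
            image.scale_um_per_px,
            channel_label=image.channel_label,
            source_id=image.source_id,
        )
    th, tw = (h // factor) * factor, (w // factor) * factor
    block = image.pixels[:th, :tw].astype(np.float64)
    block = block.reshape(th // factor, factor, tw // factor, factor).mean(axis=(1, 3))
    return CalibratedImage(
        block,
        image.scale_um_per_px * factor,
        channel_label=image.channel_label,
        source_id=image.source_id,
    )
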