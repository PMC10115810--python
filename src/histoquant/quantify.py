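"""Region-restricted whole-section summary metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage as ndi

from .images import BinaryMask, PointSet, RegionOutline, rasterize_outline

__all__ = [
    "SectionSummary",
    "area_fraction",
    "density_per_mm2",
    "intersection_over_union",
    "count_structures",
    "DEFAULT_STRUCTURE_MIN_AREA_UM2",
]

# connected components of a membrane/structure mask below this physical area
# are not counted as structures (tubule enumeration convention)
DEFAULT_STRUCTURE_MIN_AREA_UM2 = 80.0

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SectionSummary:
    section_id: str
    region_label: str
    region_area_mm2: float
    channel_label: str
    area_fraction: float | None = None
    detections_per_mm2: float | None = None


def area_fraction(mask: BinaryMask, region: BinaryMask) -> float:
    """Positive fraction of region pixels: |mask ∧ region| / |region|."""
    if mask.shape != region.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {region.shape}")
    n_region = int(np.count_nonzero(region.pixels))
    if n_region == 0:
        raise ValueError("region mask is empty")
    return int(np.count_nonzero(mask.pixels & region.pixels)) / n_region


def density_per_mm2(
    points: PointSet,
    region: RegionOutline | BinaryMask,
    scale_um_per_px: float | None = None,
) -> float:
    """Points inside the region per mm² of region area (boundary inclusive)."""
    if isinstance(region, RegionOutline):
        area_mm2 = region.area_mm2
        if area_mm2 <= 0:
            raise ValueError("region has zero area")
        if len(points) == 0:
            return 0.0
        geom = region.geometry()
        shapely.prepare(geom)
        inside = shapely.intersects_xy(geom, points.points[:, 0], points.points[:, 1])
        return int(inside.sum()) / area_mm2
    # BinaryMask region: a point lies inside iff its containing pixel is set
    scale = region.scale_um_per_px
    n_region = int(np.count_nonzero(region.pixels))
    if n_region == 0:
        raise ValueError("region mask is empty")
    area_mm2 = n_region * scale**2 / 1e6
    if len(points) == 0:
        return 0.0
    cols = np.floor(points.points[:, 0] / scale).astype(int)
    rows = np.floor(points.points[:, 1] / scale).astype(int)
    h, w = region.shape
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    count = int(region.pixels[rows[ok], cols[ok]].sum())
    return count / area_mm2


def intersection_over_union(
    mask_a: BinaryMask, mask_b: BinaryMask, region: BinaryMask | None = None
) -> float | None:
    """|a ∧ b| / |a ∨ b| within the region; empty union → flagged undefined."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    a, b = mask_a.pixels, mask_b.pixels
    if region is not None:
        if region.shape != a.shape:
            raise ValueError(f"region shape mismatch: {region.shape} vs {a.shape}")
        a = a & region.pixels
        b = b & region.pixels
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return None
    return int(np.count_nonzero(a & b)) / union


def count_structures(
    mask: BinaryMask,
    region: BinaryMask | None = None,
    min_area_um2: float = DEFAULT_STRUCTURE_MIN_AREA_UM2,
) -> int:
    """Count 8-connected components of the mask within the region whose area
    is at least ``min_area_um2``.  Components are defined on the full mask and
    assigned to the region by their centroid pixel."""
    labels, n = ndi.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return 0
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    areas = counts * mask.scale_um_per_px**2
    keep = areas >= min_area_um2
    if region is not None:
        if region.shape != mask.shape:
            raise ValueError("region shape mismatch")
        cents = ndi.center_of_mass(mask.pixels, labels, np.arange(1, n + 1))
        cents = np.rint(np.asarray(cents)).astype(int)
        cents[:, 0] = np.clip(cents[:, 0], 0, mask.shape[0] - 1)
        cents[:, 1] = np.clip(cents[:, 1], 0, mask.shape[1] - 1)
        keep &= region.pixels[cents[:, 0], cents[:, 1]]
    return int(keep.sum())


def summarize_section(
    section_id: str,
    channel_label: str,
    region_outline: RegionOutline,
    mask: BinaryMask,
    points: PointSet | None = None,
) -> SectionSummary:
    """Convenience: rasterize the region against the mask grid and compute
    both area fraction and (if points given) detection density."""
    region_mask = rasterize_outline(region_outline, mask)
    region_area_mm2 = int(np.count_nonzero(region_mask.pixels)) * mask.scale_um_per_px**2 / 1e6
    summary = SectionSummary(
        section_id=section_id,
        region_label=region_outline.label,
        region_area_mm2=region_area_mm2,
        channel_label=channel_label,
        area_fraction=area_fraction(mask, region_mask),
    )
    if points is not None:
        summary.detections_per_mm2 = density_per_mm2(points, region_mask)
    return summary
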