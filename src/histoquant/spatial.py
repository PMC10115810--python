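"""Spatial heterogeneity analysis: circular-kernel density heatmaps,
hexagonal close-packed circle tiling, per-tile density tables, correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import signal, stats
from shapely.geometry import Point

from .errors import DegenerateCorrelationError
from .images import BinaryMask, PointSet, RegionOutline

__all__ = [
    "DensityHeatmap",
    "CircleTileSet",
    "density_heatmap",
    "tile_region",
    "tile_densities",
    "pearson_correlation",
    "disk_kernel",
    "DEFAULT_TILE_RADIUS_UM",
]

DEFAULT_TILE_RADIUS_UM = 200.0


@dataclass
class DensityHeatmap:
    """Local mean of a mask over a discrete circular kernel.

    ``values`` is NaN outside the region; ``valid`` is False where the kernel
    crosses the region boundary (denominator is always the full kernel)."""

    values: np.ndarray
    valid: np.ndarray
    kernel_radius_um: float
    scale_um_per_px: float


@dataclass
class CircleTileSet:
    centers_um: np.ndarray
    radius_um: float
    region_label: str = ""

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.centers_um.shape[0]


def disk_kernel(radius_px: float) -> np.ndarray:
    """Boolean disk: pixel included iff its center is within radius_px."""
    r = int(np.floor(radius_px))
    coords = np.arange(-r, r + 1)
    d2 = coords[:, None] ** 2 + coords[None, :] ** 2
    return d2 <= radius_px**2


def density_heatmap(
    mask: BinaryMask,
    region: BinaryMask,
    radius_um: float = DEFAULT_TILE_RADIUS_UM,
) -> DensityHeatmap:
    """Per-pixel mean of the mask over a circular neighborhood.

    FFT convolution is used for speed; output is clipped to [0, 1].
    """
    if mask.shape != region.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {region.shape}")
    scale = mask.scale_um_per_px
    radius_px = radius_um / scale
    if radius_px < 1:
        raise ValueError(f"kernel radius {radius_um} um is under 1 px at {scale} um/px")
    kernel = disk_kernel(radius_px).astype(np.float64)
    n_kernel = kernel.sum()
    pad = kernel.shape[0] // 2

    def _circular_mean(data: np.ndarray) -> np.ndarray:
        # edge-replicated borders, matching classic mean-filter semantics
        padded = np.pad(data.astype(np.float64), pad, mode="edge")
        full = signal.fftconvolve(padded, kernel, mode="same")
        return full[pad:-pad, pad:-pad] / n_kernel

    values = np.clip(_circular_mean(mask.pixels), 0.0, 1.0)
    coverage = _circular_mean(region.pixels) * n_kernel
    valid = coverage >= n_kernel - 0.5
    values[~region.pixels] = np.nan
    return DensityHeatmap(
        values=values, valid=valid, kernel_radius_um=radius_um, scale_um_per_px=scale
    )


def tile_region(
    region: RegionOutline,
    radius_um: float = DEFAULT_TILE_RADIUS_UM,
    anchor_um: tuple[float, float] | None = None,
    seed: int | None = None,
) -> CircleTileSet:
    """Fill a region with non-overlapping close-packed circles.

    Candidate centers sit on a hexagonal lattice (horizontal pitch 2r, row
    spacing r·√3, alternate rows offset by r) anchored at the region
    bounding-box origin by default; ``seed`` randomizes the anchor within one
    lattice cell for sensitivity checks.  A candidate is retained iff its
    full disk lies inside the region (center inside and boundary at least r
    away), so every tile has an unbiased density denominator.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be > 0")
    geom = region.geometry()
    minx, miny, maxx, maxy = geom.bounds
    r = radius_um
    if anchor_um is not None:
        ax, ay = anchor_um
    elif seed is not None:
        rng = np.random.default_rng(seed)
        ax = minx + float(rng.uniform(0, 2 * r))
        ay = miny + float(rng.uniform(0, np.sqrt(3) * r))
    else:
        ax, ay = minx, miny
    row_pitch = np.sqrt(3) * r
    n_rows = int(np.ceil((maxy - ay) / row_pitch)) + 2
    n_cols = int(np.ceil((maxx - ax) / (2 * r))) + 2
    jj = np.arange(-1, n_rows)
    ii = np.arange(-1, n_cols)
    cy = ay + r + jj * row_pitch
    cx = ax + r + ii[None, :] * 2 * r + (jj[:, None] % 2) * r
    centers = np.column_stack([
        np.broadcast_to(cx, (len(jj), len(ii))).ravel(),
        np.repeat(cy, len(ii)),
    ])
    inbox = (
        (centers[:, 0] >= minx - r)
        & (centers[:, 0] <= maxx + r)
        & (centers[:, 1] >= miny - r)
        & (centers[:, 1] <= maxy + r)
    )
    centers = centers[inbox]
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, centers[:, 0], centers[:, 1])
    centers = centers[inside]
    boundary = geom.boundary
    kept = [c for c in centers if boundary.distance(Point(c)) >= r]
    return CircleTileSet(
        centers_um=np.asarray(kept, dtype=float).reshape(-1, 2),
        radius_um=r,
        region_label=region.label,
    )


def _mask_tile_density(mask: BinaryMask, cx: float, cy: float, r_um: float) -> float:
    scale = mask.scale_um_per_px
    h, w = mask.shape
    r_px = r_um / scale
    ccol = cx / scale - 0.5
    crow = cy / scale - 0.5
    c0 = max(int(np.floor(ccol - r_px)) - 1, 0)
    c1 = min(int(np.ceil(ccol + r_px)) + 2, w)
    r0 = max(int(np.floor(crow - r_px)) - 1, 0)
    r1 = min(int(np.ceil(crow + r_px)) + 2, h)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    d2 = (rows[:, None] - crow) ** 2 + (cols[None, :] - ccol) ** 2
    disk = d2 <= r_px**2
    n = int(disk.sum())
    if n == 0:
        return np.nan
    return float(mask.pixels[r0:r1, c0:c1][disk].sum()) / n


def tile_densities(
    tiles: CircleTileSet,
    channel_a: BinaryMask | PointSet,
    channel_b: BinaryMask | PointSet,
    scale_um_per_px: float | None = None,
    section_id: str = "",
) -> pd.DataFrame:
    """Per-tile density of two channels over each disk.

    Mask channels yield an area fraction in [0, 1]; point channels yield a
    count per mm² of disk area.  One row per tile with columns
    ``tile_index, x_um, y_um, density_a, density_b, section_id``.
    """
    shapes = [c.shape for c in (channel_a, channel_b) if isinstance(c, BinaryMask)]
    if len(shapes) == 2 and shapes[0] != shapes[1]:
        raise ValueError(f"channel shapes differ: {shapes[0]} vs {shapes[1]}")
    r = tiles.radius_um
    disk_area_mm2 = np.pi * r**2 / 1e6

    def _density(channel, cx, cy) -> float:
        if isinstance(channel, BinaryMask):
            return _mask_tile_density(channel, cx, cy, r)
        pts = channel.points
        if pts.shape[0] == 0:
            return 0.0
        d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        return float((d2 <= r**2).sum()) / disk_area_mm2

    rows = []
    for i, (cx, cy) in enumerate(tiles.centers_um):
        rows.append(
            {
                "tile_index": i,
                "x_um": cx,
                "y_um": cy,
                "density_a": _density(channel_a, cx, cy),
                "density_b": _density(channel_b, cx, cy),
                "section_id": section_id,
            }
        )
    return pd.DataFrame(
        rows, columns=["tile_index", "x_um", "y_um", "density_a", "density_b", "section_id"]
    )


def pearson_correlation(
    table: pd.DataFrame,
    col_a: str = "density_a",
    col_b: str = "density_b",
) -> tuple[float, int, float]:
    """Sample Pearson r of the paired densities with its t-transform p-value.

    Returns ``(r, n, p)``.  Rows with missing values are dropped.
    """
    data = table[[col_a, col_b]].dropna()
    n = len(data)
    if n < 3:
        raise DegenerateCorrelationError(f"need >= 3 paired observations, got {n}")
    a = data[col_a].to_numpy(float)
    b = data[col_b].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateCorrelationError("constant column: correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), n, float(res.pvalue)
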