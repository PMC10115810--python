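"""Calibrated rasters, masks, outlines and point sets, plus their file I/O.

Conventions used throughout the toolkit:

* pixel indices are 0-based ``(row, col)``;
* physical coordinates are pixel **centers** in micrometres, with
  ``x = (col + 0.5) * scale`` and ``y = (row + 0.5) * scale``;
* masks are stored on disk as 8-bit TIFFs with values 0/255;
* outlines are GeoJSON polygons in micrometres; point sets are CSV with
  columns ``x_um,y_um`` (an optional ``area_um2`` column is preserved).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

from .errors import EmptyRegionError, FormatError

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "RegionOutline",
    "PointSet",
    "ROIBox",
    "read_calibrated_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_outline",
    "write_outline",
    "read_points",
    "write_points",
    "rasterize_outline",
    "make_montage",
    "parse_section_filename",
]


@dataclass
class CalibratedImage:
    """A 2-D grayscale intensity raster with an isotropic μm/pixel scale."""

    pixels: np.ndarray
    scale_um_per_px: float
    channel_label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError(
                f"expected a non-empty 2-D raster, got shape {self.pixels.shape}"
            )
        if not (self.scale_um_per_px > 0):
            raise ValueError(f"scale_um_per_px must be > 0, got {self.scale_um_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the raster in μm."""
        h, w = self.pixels.shape
        return w * self.scale_um_per_px, h * self.scale_um_per_px


@dataclass
class BinaryMask:
    """A per-pixel positive/negative segmentation aligned to a CalibratedImage."""

    pixels: np.ndarray
    scale_um_per_px: float
    source_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError(
                f"expected a non-empty 2-D mask, got shape {self.pixels.shape}"
            )
        if not (self.scale_um_per_px > 0):
            raise ValueError(f"scale_um_per_px must be > 0, got {self.scale_um_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def positive_fraction(self) -> float:
        return float(self.pixels.mean())

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.scale_um_per_px**2


@dataclass
class RegionOutline:
    """Polygon(s), vertices in μm, delimiting an analyzed tissue compartment."""

    polygons: MultiPolygon
    label: str = ""

    def __post_init__(self) -> None:
        geom = self.polygons
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        elif isinstance(geom, (list, tuple)):
            geom = MultiPolygon([g if isinstance(g, Polygon) else Polygon(g) for g in geom])
        if not isinstance(geom, MultiPolygon):
            raise TypeError(f"polygons must be shapely (Multi)Polygon, got {type(geom)}")
        if not geom.is_valid:
            raise ValueError("outline polygons must be simple (non-self-intersecting)")
        if not geom.area > 0:
            raise ValueError("outline must enclose a positive area")
        self.polygons = geom

    @property
    def area_um2(self) -> float:
        return float(self.polygons.area)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    def geometry(self) -> MultiPolygon:
        return self.polygons


@dataclass
class PointSet:
    """Detection/annotation centroids in μm with a provenance label.

    ``areas_um2`` optionally carries per-point particle areas (aligned to
    ``points``); it is preserved by CSV round trips when present.
    """

    points: np.ndarray
    source_label: str = ""
    areas_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        self.points = pts
        if self.areas_um2 is not None:
            self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
            if self.areas_um2.shape[0] != pts.shape[0]:
                raise ValueError("areas_um2 must align with points")

    def __len__(self) -> int:
        return self.points.shape[0]

    def has_duplicates(self, tol_um: float = 1e-9) -> bool:
        """QC check: True if any two points coincide within ``tol_um``."""
        if len(self) < 2:
            return False
        rounded = np.round(self.points / max(tol_um, 1e-12)).astype(np.int64)
        return len(np.unique(rounded, axis=0)) < len(self)


@dataclass
class ROIBox:
    """An axis-aligned pixel box; must lie fully inside its parent image."""

    origin_px: tuple[int, int]
    size_px: tuple[int, int]

    def __post_init__(self) -> None:
        if self.size_px[0] <= 0 or self.size_px[1] <= 0:
            raise ValueError(f"box size must be positive, got {self.size_px}")

    def validate_inside(self, shape: tuple[int, int]) -> None:
        r, c = self.origin_px
        h, w = self.size_px
        if r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
            raise ValueError(f"ROI {self} does not fit inside image of shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin_px
        h, w = self.size_px
        return slice(r, r + h), slice(c, c + w)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FILENAME_FIELDS = (
    "genotype",
    "reporter",
    "sex",
    "tag",
    "condition",
    "stain",
)


def read_calibrated_image(
    path: str | Path,
    scale_um_per_px: float,
    channel_label: str = "",
) -> CalibratedImage:
    """Read a single-channel grayscale TIFF and attach a μm/pixel scale."""
    if not (scale_um_per_px > 0):
        raise ValueError(f"scale_um_per_px must be > 0, got {scale_um_per_px}")
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(
            f"{path} is not single-channel grayscale (shape after squeeze: {data.shape})"
        )
    if data.size == 0:
        raise FormatError(f"{path} contains a zero-sized image")
    meta = parse_section_filename(path.name)
    return CalibratedImage(
        pixels=data,
        scale_um_per_px=float(scale_um_per_px),
        channel_label=channel_label or meta.get("stain", ""),
        source_id=meta["source_id"],
    )


def write_image(path: str | Path, image: CalibratedImage) -> None:
    """Write intensities to TIFF; float data is stored as float32."""
    data = image.pixels
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)


def read_mask(path: str | Path, scale_um_per_px: float, source_label: str = "") -> BinaryMask:
    data = np.squeeze(tifffile.imread(path))
    if data.ndim != 2:
        raise FormatError(f"{path} is not a single-channel mask")
    return BinaryMask(data > 0, scale_um_per_px, source_label or Path(path).stem)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(path, np.where(mask.pixels, 255, 0).astype(np.uint8))


def read_outline(path: str | Path, label: str = "") -> RegionOutline:
    """Read GeoJSON polygons (μm coordinates) into a RegionOutline."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms = []
    if doc.get("type") == "FeatureCollection":
        for feat in doc["features"]:
            geoms.append(shape(feat["geometry"]))
    elif doc.get("type") == "Feature":
        geoms.append(shape(doc["geometry"]))
    else:
        geoms.append(shape(doc))
    merged = unary_union(geoms)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    return RegionOutline(merged, label=label or Path(path).stem)


def write_outline(path: str | Path, outline: RegionOutline) -> None:
    doc = {
        "type": "Feature",
        "properties": {"label": outline.label, "unit": "um"},
        "geometry": mapping(outline.polygons),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_points(path: str | Path, source_label: str = "") -> PointSet:
    df = pd.read_csv(path)
    if "x_um" not in df.columns or "y_um" not in df.columns:
        raise FormatError(f"{path} must have columns x_um,y_um")
    areas = df["area_um2"].to_numpy() if "area_um2" in df.columns else None
    return PointSet(
        df[["x_um", "y_um"]].to_numpy(float),
        source_label=source_label or Path(path).stem,
        areas_um2=areas,
    )


def write_points(path: str | Path, points: PointSet) -> None:
    df = pd.DataFrame(points.points, columns=["x_um", "y_um"])
    if points.areas_um2 is not None:
        df["area_um2"] = points.areas_um2
    df.to_csv(path, index=False)


def parse_section_filename(name: str) -> dict[str, str]:
    """Parse the six-field underscore file-name convention into a record.

    Unknown layouts pass through with only ``source_id`` (the file stem) set.
    """
    stem = Path(name).stem
    record = {"source_id": stem}
    parts = stem.split("_")
    if len(parts) == len(_FILENAME_FIELDS) and all(re.match(r"^[\w\-+.]+$", p) for p in parts):
        record.update(dict(zip(_FILENAME_FIELDS, parts)))
    return record


# ---------------------------------------------------------------------------
# Rasterization and QC montage
# ---------------------------------------------------------------------------


def rasterize_outline(outline: RegionOutline, template: CalibratedImage | BinaryMask) -> BinaryMask:
    """Rasterize an outline onto the template grid (pixel-center inclusion).

    A pixel is positive iff its center lies strictly inside a polygon and
    outside its holes.
    """
    h, w = template.shape
    scale = template.scale_um_per_px
    geom = outline.geometry()
    minx, miny, maxx, maxy = geom.bounds
    if maxx <= 0 or maxy <= 0 or minx >= w * scale or miny >= h * scale:
        raise EmptyRegionError(
            f"outline bounds {geom.bounds} do not overlap image extent "
            f"({w * scale} x {h * scale} um)"
        )
    xs = (np.arange(w) + 0.5) * scale
    ys = (np.arange(h) + 0.5) * scale
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(h, w)
    if not inside.any():
        raise EmptyRegionError("outline rasterizes to an empty mask on this template")
    return BinaryMask(inside, scale, source_label=outline.label)


def _preview(mask: BinaryMask, tile_px: int) -> np.ndarray:
    """Down-sample a mask to fit a square preview tile, preserving aspect."""
    h, w = mask.shape
    step = max(1, int(np.ceil(max(h, w) / tile_px)))
    small = mask.pixels[::step, ::step]
    out = np.zeros((tile_px, tile_px), dtype=np.uint8)
    sh, sw = min(small.shape[0], tile_px), min(small.shape[1], tile_px)
    out[:sh, :sw] = np.where(small[:sh, :sw], 200, 0)
    return out


def make_montage(
    masks: Sequence[BinaryMask],
    outlines: Sequence[RegionOutline] | None = None,
    columns: int = 4,
    tile_px: int = 256,
) -> CalibratedImage:
    """Assemble a row-major grid of down-sampled mask previews for human QC.

    Outline boundaries, when supplied (one per mask), are burned in at full
    intensity on top of the corresponding preview.
    """
    if not masks:
        raise ValueError("make_montage requires at least one mask")
    if columns < 1:
        raise ValueError("columns must be >= 1")
    if outlines is not None and len(outlines) not in (0, len(masks)):
        raise ValueError("outlines must be empty or match masks 1:1")
    rows = int(np.ceil(len(masks) / columns))
    grid = np.zeros((rows * tile_px, columns * tile_px), dtype=np.uint8)
    for i, mask in enumerate(masks):
        tile = _preview(mask, tile_px)
        if outlines:
            tile = _burn_outline(tile, mask, outlines[i], tile_px)
        r, c = divmod(i, columns)
        grid[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px] = tile
    return CalibratedImage(grid, scale_um_per_px=1.0, channel_label="qc_montage")


def _burn_outline(tile: np.ndarray, mask: BinaryMask, outline: RegionOutline, tile_px: int) -> np.ndarray:
    h, w = mask.shape
    step = max(1, int(np.ceil(max(h, w) / tile_px)))
    scale = mask.scale_um_per_px * step
    tile = tile.copy()
    for poly in outline.geometry().geoms:
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            coords = np.asarray(ring.coords)
            # densify so the burned boundary is continuous at preview scale
            seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            n = np.maximum((seg / scale).astype(int), 1)
            dense = [coords[0]]
            for (p0, p1), k in zip(zip(coords[:-1], coords[1:]), n):
                ts = np.linspace(0, 1, k + 1)[1:, None]
                dense.append(p0 + ts * (np.asarray(p1) - np.asarray(p0)))
            pts = np.vstack(dense)
            cols = (pts[:, 0] / scale).astype(int)
            rws = (pts[:, 1] / scale).astype(int)
            keep = (cols >= 0) & (cols < tile.shape[1]) & (rws >= 0) & (rws < tile.shape[0])
            tile[rws[keep], cols[keep]] = 255
    return tile
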