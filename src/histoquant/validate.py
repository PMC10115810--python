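"""Segmentation validation: ROI sampling, pixel metrics, point matching,
detection Dice, and observer-comparison tables.

Degenerate (0/0) metrics are reported as ``None`` — flagged missing, never
coerced to 0 — so summaries cannot be silently biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist

from .errors import SamplingError
from .images import BinaryMask, CalibratedImage, PointSet, RegionOutline, ROIBox

__all__ = [
    "PixelConfusion",
    "PixelMetrics",
    "MatchResult",
    "RoiSample",
    "pixel_confusion",
    "pixel_metrics",
    "match_points",
    "detection_dice",
    "sample_validation_rois",
    "apply_inclusion_rules",
    "observer_report",
    "DEFAULT_MATCH_RADIUS_UM",
]

DEFAULT_MATCH_RADIUS_UM = 5.0
MEMBRANE_FRACTION_BOUNDS = (0.1, 0.9)
MIN_NUCLEI_FOR_INCLUSION = 5


@dataclass
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PixelMetrics:
    """Sensitivity, specificity and Dice; ``None`` marks an undefined 0/0."""

    sensitivity: float | None
    specificity: float | None
    dice: float | None
    confusion: PixelConfusion


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]
    unmatched_reference: list[int]
    unmatched_comparator: list[int]
    radius_um: float

    @property
    def n_reference(self) -> int:
        return len(self.pairs) + len(self.unmatched_reference)

    @property
    def n_comparator(self) -> int:
        return len(self.pairs) + len(self.unmatched_comparator)


@dataclass
class RoiSample:
    roi: ROIBox
    section_id: str
    included: bool = True
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.included and self.exclusion_reason is not None:
            raise ValueError("included samples cannot carry an exclusion reason")


def pixel_confusion(reference: BinaryMask, comparator: BinaryMask) -> PixelConfusion:
    if reference.shape != comparator.shape:
        raise ValueError(
            f"mask shapes differ: {reference.shape} vs {comparator.shape}"
        )
    ref = reference.pixels
    comp = comparator.pixels
    tp = int(np.count_nonzero(ref & comp))
    fp = int(np.count_nonzero(~ref & comp))
    fn = int(np.count_nonzero(ref & ~comp))
    tn = int(np.count_nonzero(~ref & ~comp))
    return PixelConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def pixel_metrics(reference: BinaryMask, comparator: BinaryMask) -> PixelMetrics:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    Dice = 2·TP/((TP+FP)+(TP+FN)); comparator is scored against reference."""
    c = pixel_confusion(reference, comparator)
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    denom = (c.tp + c.fp) + (c.tp + c.fn)
    dice = 2 * c.tp / denom if denom > 0 else None
    return PixelMetrics(sensitivity=sens, specificity=spec, dice=dice, confusion=c)


def match_points(
    reference: PointSet,
    comparator: PointSet,
    radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> MatchResult:
    """One-to-one point matching, globally nearest pair first.

    Repeatedly fixes the smallest-distance unmatched (reference, comparator)
    pair with distance ≤ radius; each point matches at most once.  Ties break
    on lower reference index, then lower comparator index, making the result
    deterministic and order-invariant.
    """
    if not radius_um > 0:
        raise ValueError(f"radius_um must be > 0, got {radius_um}")
    nr, nc = len(reference), len(comparator)
    if nr == 0 or nc == 0:
        return MatchResult([], list(range(nr)), list(range(nc)), radius_um)
    dist = cdist(reference.points, comparator.points)
    ri, ci = np.nonzero(dist <= radius_um)
    dv = dist[ri, ci]
    order = np.lexsort((ci, ri, dv))
    ref_used = np.zeros(nr, dtype=bool)
    comp_used = np.zeros(nc, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(ri[k]), int(ci[k])
        if ref_used[i] or comp_used[j]:
            continue
        ref_used[i] = True
        comp_used[j] = True
        pairs.append((i, j, float(dv[k])))
    return MatchResult(
        pairs=pairs,
        unmatched_reference=[i for i in range(nr) if not ref_used[i]],
        unmatched_comparator=[j for j in range(nc) if not comp_used[j]],
        radius_um=radius_um,
    )


def detection_dice(match: MatchResult) -> float | None:
    """2·|pairs| / (n_ref + n_comp); both sets empty → flagged undefined."""
    denom = match.n_reference + match.n_comparator
    if denom == 0:
        return None
    return 2 * len(match.pairs) / denom


def sample_validation_rois(
    sections: Sequence[tuple[CalibratedImage, RegionOutline]],
    roi_size_px: tuple[int, int],
    candidates_per_section: int = 5,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[RoiSample]:
    """Per section, draw ``candidates_per_section`` ROIs with center uniform
    inside the region outline, then retain exactly one by a second seeded
    draw.  Deterministic given the seed."""
    if candidates_per_section < 1:
        raise ValueError("candidates_per_section must be >= 1")
    h_px, w_px = roi_size_px
    rng = np.random.default_rng(seed)
    retained: list[RoiSample] = []
    for image, outline in sections:
        ih, iw = image.shape
        scale = image.scale_um_per_px
        if h_px > ih or w_px > iw:
            raise SamplingError(
                f"ROI {roi_size_px} does not fit in section of shape {image.shape}"
            )
        geom = outline.geometry()
        shapely.prepare(geom)
        candidates: list[ROIBox] = []
        attempts = 0
        while len(candidates) < candidates_per_section:
            if attempts >= max_attempts:
                raise SamplingError(
                    f"could not place {candidates_per_section} ROIs of size "
                    f"{roi_size_px} with center in region {outline.label!r}"
                )
            attempts += 1
            r0 = int(rng.integers(0, ih - h_px + 1))
            c0 = int(rng.integers(0, iw - w_px + 1))
            cy = (r0 + h_px / 2) * scale
            cx = (c0 + w_px / 2) * scale
            if shapely.contains_xy(geom, cx, cy):
                candidates.append(ROIBox((r0, c0), (h_px, w_px)))
        pick = int(rng.integers(0, candidates_per_section))
        retained.append(RoiSample(roi=candidates[pick], section_id=image.source_id))
    return retained


def apply_inclusion_rules(
    roi_payload: BinaryMask | PointSet,
    stain_class: str,
) -> tuple[bool, str | None]:
    """Reference-side inclusion rules for validation ROIs.

    membrane: positive area fraction within [0.1, 0.9] (inclusive);
    nuclear: at least 5 reference nuclei.
    """
    if stain_class == "membrane":
        if not isinstance(roi_payload, BinaryMask):
            raise ValueError("membrane inclusion needs a BinaryMask payload")
        frac = roi_payload.positive_fraction()
        lo, hi = MEMBRANE_FRACTION_BOUNDS
        if frac < lo:
            return False, f"area fraction below {lo}"
        if frac > hi:
            return False, f"area fraction above {hi}"
        return True, None
    if stain_class == "nuclear":
        if not isinstance(roi_payload, PointSet):
            raise ValueError("nuclear inclusion needs a PointSet payload")
        if len(roi_payload) < MIN_NUCLEI_FOR_INCLUSION:
            return False, f"fewer than {MIN_NUCLEI_FOR_INCLUSION} reference nuclei"
        return True, None
    raise ValueError(f"unknown stain_class {stain_class!r}")


def _metric_rows(
    name: str,
    reference,
    payloads,
    stain_class: str,
    radius_um: float,
) -> list[dict]:
    rows = []
    for i, (ref, comp) in enumerate(zip(reference, payloads)):
        if stain_class == "membrane":
            m = pixel_metrics(ref, comp)
            rows.append(
                {
                    "comparator": name,
                    "roi_index": i,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "dice": m.dice,
                }
            )
        else:
            match = match_points(ref, comp, radius_um)
            rows.append(
                {
                    "comparator": name,
                    "roi_index": i,
                    "n_reference": match.n_reference,
                    "n_comparator": match.n_comparator,
                    "n_matched": len(match.pairs),
                    "dice": detection_dice(match),
                }
            )
    return rows


def observer_report(
    reference: Sequence[BinaryMask] | Sequence[PointSet],
    comparators: Mapping[str, Sequence[BinaryMask] | Sequence[PointSet]],
    stain_class: str,
    radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> pd.DataFrame:
    """Per-ROI metric rows per comparator plus median/IQR summary rows.

    Undefined metrics stay missing (NaN in the table) and are excluded from
    the summaries.
    """
    if stain_class not in ("membrane", "nuclear"):
        raise ValueError(f"unknown stain_class {stain_class!r}")
    n = len(reference)
    for name, payloads in comparators.items():
        if len(payloads) != n:
            raise ValueError(
                f"comparator {name!r} covers {len(payloads)} ROIs, reference has {n}"
            )
    rows: list[dict] = []
    for name, payloads in comparators.items():
        rows.extend(_metric_rows(name, reference, payloads, stain_class, radius_um))
    per_roi = pd.DataFrame(rows)
    summaries = []
    metric_cols = [
        c for c in ("sensitivity", "specificity", "dice") if c in per_roi.columns
    ]
    for name, grp in per_roi.groupby("comparator", sort=False):
        row = {"comparator": name, "roi_index": pd.NA, "row_kind": "summary"}
        for col in metric_cols:
            vals = grp[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else pd.NA
            if len(vals):
                row[f"{col}_iqr"] = vals.quantile(0.75) - vals.quantile(0.25)
            else:
                row[f"{col}_iqr"] = pd.NA
        summaries.append(row)
    per_roi["row_kind"] = "roi"
    return pd.concat([per_roi, pd.DataFrame(summaries)], ignore_index=True)
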