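"""Classic (non-deep-learning) segmentation backends.

Two families are provided:

* histogram auto-thresholding (``default_isodata``, ``otsu``, ``triangle``,
  ``mean``, ``li``), whole-section or per-ROI, on a 256-bin histogram of the
  restricted pixels — mirroring common 8-bit thresholder semantics while
  binning (not truncating) wider dtypes;
* a random-forest pixel classifier over a multi-scale filter bank
  (Gaussian, Laplacian-of-Gaussian, gradient magnitude, structure-tensor
  eigenvalues).

Masks are "strictly above threshold": a pixel equal to the threshold value
is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from scipy.special import xlogy
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .errors import DegenerateHistogramError, ModelStateError
from .images import BinaryMask, CalibratedImage, ROIBox

__all__ = [
    "THRESHOLD_METHODS",
    "ThresholdResult",
    "RoiThreshold",
    "auto_threshold",
    "threshold_per_roi",
    "threshold_from_histogram",
    "PixelClassifier",
    "train_pixel_classifier",
    "predict_pixel_classifier",
    "DEFAULT_FEATURE_SPEC",
]

N_BINS = 256

THRESHOLD_METHODS = ("default_isodata", "otsu", "triangle", "mean", "li")


@dataclass
class ThresholdResult:
    """A computed threshold: intensity value, bin index, method and mode."""

    threshold: float
    method: str
    mode: str
    bin_index: int
    histogram: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)


@dataclass
class RoiThreshold:
    """Per-ROI thresholding outcome; degenerate ROIs are flagged, not fatal."""

    roi: ROIBox
    result: ThresholdResult | None
    mask: BinaryMask
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Histogram threshold algorithms (operate on a 256-bin count vector, return
# the bin index t such that bins > t are foreground)
# ---------------------------------------------------------------------------


def _isodata_intermeans(h: np.ndarray) -> int:
    """Iterative intermeans ("default" IsoData variant of the classic tool).

    Walks a split point upward from the lowest occupied bin; at each split
    the candidate level is the mean of the two class means; stops once the
    split index passes that candidate.
    """
    n = len(h)
    lo = 0
    while h[lo] == 0 and lo < n - 1:
        lo += 1
    hi = n - 1
    while h[hi] == 0 and hi > 0:
        hi -= 1
    if lo >= hi:
        return n // 2
    moving = lo
    idx = np.arange(n, dtype=np.float64)
    while True:
        sum1 = float((idx[lo : moving + 1] * h[lo : moving + 1]).sum())
        sum2 = float(h[lo : moving + 1].sum())
        sum3 = float((idx[moving + 1 : hi + 1] * h[moving + 1 : hi + 1]).sum())
        sum4 = float(h[moving + 1 : hi + 1].sum())
        result = (sum1 / sum2 + sum3 / sum4) / 2.0 if sum2 > 0 and sum4 > 0 else moving
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return int(round(result))


def _otsu(h: np.ndarray) -> int:
    """Maximize between-class variance; first argmax wins."""
    idx = np.arange(len(h), dtype=np.float64)
    total = h.sum()
    w0 = np.cumsum(h)
    m0 = np.cumsum(idx * h)
    mean_total = m0[-1] / total
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    return int(np.argmax(var_between))


def _mean(h: np.ndarray) -> int:
    idx = np.arange(len(h), dtype=np.float64)
    return int(np.floor((idx * h).sum() / h.sum()))


def _triangle(h: np.ndarray) -> int:
    """Geometric triangle method: maximize distance from the histogram to the
    peak-to-tail chord, flipping so the long tail lies to the right."""
    data = h.astype(np.float64).copy()
    n = len(data)
    nz = np.nonzero(data)[0]
    mn = max(nz[0] - 1, 0)
    mx2 = min(nz[-1] + 1, n - 1)
    peak = int(np.argmax(data))
    inverted = (peak - mn) < (mx2 - peak)
    if inverted:
        data = data[::-1]
        mn, mx2 = n - 1 - mx2, n - 1 - mn
        peak = n - 1 - peak
    if mn == peak:
        split = mn
    else:
        nx = data[peak]
        ny = float(mn - peak)
        d = float(np.hypot(nx, ny))
        nx /= d
        ny /= d
        d = nx * mn + ny * data[mn]
        split, split_dist = mn, 0.0
        for i in range(mn + 1, peak + 1):
            dist = nx * i + ny * data[i] - d
            if dist > split_dist:
                split, split_dist = i, dist
        split -= 1
    if inverted:
        split = n - 1 - split
    return int(split)


def _li_cross_entropy(h: np.ndarray) -> np.ndarray:
    """Li cross-entropy criterion for every split t (class 0 = bins <= t)."""
    idx = np.arange(len(h), dtype=np.float64)
    a = np.cumsum(idx * h)  # intensity mass below (inclusive)
    nlo = np.cumsum(h).astype(np.float64)
    a_tot, n_tot = a[-1], nlo[-1]
    a_hi = a_tot - a
    n_hi = n_tot - nlo
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_lo = np.where(nlo > 0, a / nlo, 0.0)
        mu_hi = np.where(n_hi > 0, a_hi / n_hi, 0.0)
    eta = -(xlogy(a, mu_lo) + xlogy(a_hi, mu_hi))
    return eta


def _li(h: np.ndarray) -> int:
    """Minimum cross-entropy threshold, chosen by exhaustive criterion scan."""
    eta = _li_cross_entropy(h.astype(np.float64))
    # exclude splits with an empty class on either side
    nlo = np.cumsum(h)
    valid = (nlo > 0) & (nlo < h.sum())
    eta = np.where(valid, eta, np.inf)
    if not np.isfinite(eta).any():
        return len(h) // 2
    return int(np.argmin(eta))


_METHOD_FUNCS = {
    "default_isodata": _isodata_intermeans,
    "otsu": _otsu,
    "triangle": _triangle,
    "mean": _mean,
    "li": _li,
}


def threshold_from_histogram(counts: np.ndarray, method: str) -> int:
    """Return the threshold bin index for a 256-bin histogram."""
    if method not in _METHOD_FUNCS:
        raise ValueError(f"unknown method {method!r}; choose from {THRESHOLD_METHODS}")
    counts = np.asarray(counts)
    if counts.sum() <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram needs >= 2 occupied bins")
    return _METHOD_FUNCS[method](counts)


def auto_threshold(
    image: CalibratedImage,
    method: str = "default_isodata",
    restrict: BinaryMask | None = None,
    mode: str = "whole_section",
) -> tuple[ThresholdResult, BinaryMask]:
    """Auto-threshold an image from the 256-bin histogram of in-restriction
    pixels; the mask covers the whole image (pixels strictly above threshold).
    """
    if method not in _METHOD_FUNCS:
        raise ValueError(f"unknown method {method!r}; choose from {THRESHOLD_METHODS}")
    pixels = image.pixels
    values = pixels[restrict.pixels] if restrict is not None else pixels.ravel()
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise DegenerateHistogramError("restriction selects no pixels")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateHistogramError("constant image: cannot threshold")
    counts, edges = np.histogram(values, bins=N_BINS, range=(lo, hi))
    t = threshold_from_histogram(counts, method)
    threshold = float(edges[t + 1])
    result = ThresholdResult(
        threshold=threshold,
        method=method,
        mode=mode,
        bin_index=t,
        histogram=counts,
        bin_edges=edges,
    )
    mask = BinaryMask(pixels > threshold, image.scale_um_per_px, source_label=f"threshold:{method}")
    return result, mask


def threshold_per_roi(
    image: CalibratedImage,
    rois: Sequence[ROIBox],
    method: str = "default_isodata",
) -> list[RoiThreshold]:
    """Apply ``auto_threshold`` independently to each ROI crop.

    Degenerate (constant-intensity) ROIs yield a flagged result with an
    empty mask instead of raising.
    """
    out: list[RoiThreshold] = []
    for roi in rois:
        roi.validate_inside(image.shape)
        crop = CalibratedImage(
            image.pixels[roi.slices()],
            image.scale_um_per_px,
            channel_label=image.channel_label,
            source_id=image.source_id,
        )
        try:
            result, mask = auto_threshold(crop, method, mode="per_roi")
            out.append(RoiThreshold(roi=roi, result=result, mask=mask))
        except DegenerateHistogramError:
            empty = BinaryMask(
                np.zeros(crop.shape, dtype=bool),
                image.scale_um_per_px,
                source_label=f"threshold:{method}:degenerate",
            )
            out.append(RoiThreshold(roi=roi, result=None, mask=empty, degenerate=True))
    return out


# ---------------------------------------------------------------------------
# Random-forest pixel classifier
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0)
_FEATURE_NAMES = ("gaussian", "log", "gradient_magnitude", "st_eig_large", "st_eig_small")
DEFAULT_FEATURE_SPEC: tuple[tuple[str, float], ...] = tuple(
    (name, sigma) for sigma in DEFAULT_FEATURE_SCALES for name in _FEATURE_NAMES
)

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 2


def _feature_plane(pixels: np.ndarray, name: str, sigma: float) -> np.ndarray:
    if name == "gaussian":
        return ndi.gaussian_filter(pixels, sigma)
    if name == "log":
        return ndi.gaussian_laplace(pixels, sigma)
    if name == "gradient_magnitude":
        return ndi.gaussian_gradient_magnitude(pixels, sigma)
    if name in ("st_eig_large", "st_eig_small"):
        tensor = structure_tensor(pixels, sigma=sigma, order="rc")
        eigs = structure_tensor_eigenvalues(tensor)
        return eigs[0] if name == "st_eig_large" else eigs[1]
    raise ValueError(f"unknown feature {name!r}")


def compute_feature_stack(
    pixels: np.ndarray, feature_spec: Sequence[tuple[str, float]] = DEFAULT_FEATURE_SPEC
) -> np.ndarray:
    """(H, W, n_features) float32 stack of filter responses."""
    pixels = np.asarray(pixels, dtype=np.float32)
    planes = [_feature_plane(pixels, name, sigma) for name, sigma in feature_spec]
    return np.stack(planes, axis=-1).astype(np.float32)


class PixelClassifier:
    """Random-forest per-pixel classifier over a multi-scale filter bank."""

    def __init__(
        self,
        n_trees: int = 100,
        feature_spec: Sequence[tuple[str, float]] = DEFAULT_FEATURE_SPEC,
        seed: int = 0,
    ) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not feature_spec:
            raise ValueError("feature_spec must be non-empty")
        self.n_trees = n_trees
        self.feature_spec = tuple(feature_spec)
        self.seed = seed
        self._forest: RandomForestClassifier | None = None

    @property
    def trained(self) -> bool:
        return self._forest is not None

    def fit(
        self,
        images: Sequence[CalibratedImage],
        annotations: Sequence[np.ndarray],
    ) -> "PixelClassifier":
        """Train from sparse label masks (1 = positive, 2 = negative, 0 = unlabeled)."""
        if len(images) != len(annotations):
            raise ValueError("images and annotations must align 1:1")
        xs, ys = [], []
        for image, labels in zip(images, annotations):
            labels = np.asarray(labels)
            if labels.shape != image.shape:
                raise ValueError("annotation shape must match its image")
            sel = labels != 0
            if not sel.any():
                continue
            stack = compute_feature_stack(image.pixels, self.feature_spec)
            xs.append(stack[sel])
            ys.append(labels[sel])
        if not xs:
            raise ValueError("no labeled pixels supplied")
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        present = set(np.unique(y).tolist())
        if not {POSITIVE_LABEL, NEGATIVE_LABEL} <= present:
            raise ValueError(
                f"training requires both positive and negative labels, got classes {sorted(present)}"
            )
        forest = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        forest.fit(x, y)
        self._forest = forest
        return self

    def predict(self, image: CalibratedImage) -> BinaryMask:
        """Argmax class per pixel; positive class becomes mask-true."""
        if self._forest is None:
            raise ModelStateError("classifier has not been trained")
        stack = compute_feature_stack(image.pixels, self.feature_spec)
        h, w, f = stack.shape
        pred = self._forest.predict(stack.reshape(-1, f)).reshape(h, w)
        return BinaryMask(
            pred == POSITIVE_LABEL, image.scale_um_per_px, source_label="pixel_classifier"
        )

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "n_trees": self.n_trees,
                "feature_spec": self.feature_spec,
                "seed": self.seed,
                "forest": self._forest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        blob = joblib.load(path)
        model = cls(blob["n_trees"], blob["feature_spec"], blob["seed"])
        model._forest = blob["forest"]
        return model


def train_pixel_classifier(
    images: Sequence[CalibratedImage],
    annotations: Sequence[np.ndarray],
    n_trees: int = 100,
    feature_spec: Sequence[tuple[str, float]] = DEFAULT_FEATURE_SPEC,
    seed: int = 0,
) -> PixelClassifier:
    return PixelClassifier(n_trees=n_trees, feature_spec=feature_spec, seed=seed).fit(
        images, annotations
    )


def predict_pixel_classifier(model: PixelClassifier, image: CalibratedImage) -> BinaryMask:
    return model.predict(image)
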