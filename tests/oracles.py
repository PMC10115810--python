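"""Independent brute-force oracles used by the test-suite and the
acceptance report.  These deliberately avoid the library code paths they
check: naive scans, shift-stack morphology, exhaustive matching.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.special import xlogy

# ---------------------------------------------------------------------------
# grayscale opening with a ball-shaped structuring element (shift-stack)
# ---------------------------------------------------------------------------


def ball_heights(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, heights) of a ball structuring element."""
    offs, hts = [], []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            d2 = di * di + dj * dj
            if d2 <= radius * radius:
                offs.append((di, dj))
                hts.append(np.sqrt(radius * radius - d2))
    return np.asarray(offs), np.asarray(hts)


def _shift(padded: np.ndarray, di: int, dj: int, r: int, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return padded[r + di : r + di + h, r + dj : r + dj + w]


def brute_ball_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Erosion then dilation with the ball element, nearest-edge padding."""
    image = np.asarray(image, dtype=np.float64)
    offs, hts = ball_heights(radius)
    padded = np.pad(image, radius, mode="edge")
    eroded = np.min(
        [_shift(padded, di, dj, radius, image.shape) - g for (di, dj), g in zip(offs, hts)],
        axis=0,
    )
    padded = np.pad(eroded, radius, mode="edge")
    dilated = np.max(
        [_shift(padded, di, dj, radius, image.shape) + g for (di, dj), g in zip(offs, hts)],
        axis=0,
    )
    return dilated


# ---------------------------------------------------------------------------
# threshold criterion scans (all loops, no cumsums)
# ---------------------------------------------------------------------------


def otsu_scan(h: np.ndarray) -> int:
    n = len(h)
    idx = np.arange(n, dtype=float)
    total = h.sum()
    best, best_t = -1.0, 0
    for t in range(n):
        w0 = h[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((idx[: t + 1] * h[: t + 1]).sum()) / w0
        mu1 = float((idx[t + 1 :] * h[t + 1 :]).sum()) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, t
    return best_t


def mean_scan(h: np.ndarray) -> int:
    total = weighted = 0.0
    for i, c in enumerate(h):
        total += c
        weighted += i * c
    return int(np.floor(weighted / total))


def li_scan(h: np.ndarray) -> int:
    n = len(h)
    total = h.sum()
    best, best_t = np.inf, n // 2
    for t in range(n):
        n_lo = h[: t + 1].sum()
        if n_lo == 0 or n_lo == total:
            continue
        a_lo = float(sum(i * h[i] for i in range(t + 1)))
        a_hi = float(sum(i * h[i] for i in range(t + 1, n)))
        mu_lo = a_lo / n_lo
        mu_hi = a_hi / (total - n_lo)
        eta = -(xlogy(a_lo, mu_lo) + xlogy(a_hi, mu_hi))
        if eta < best:
            best, best_t = eta, t
    return best_t


def li_fixed_point(h: np.ndarray, max_iter: int = 200) -> float:
    """Li & Tam iteration; returns the continuous fixed point."""
    idx = np.arange(len(h), dtype=float)
    t = float((idx * h).sum() / h.sum())
    for _ in range(max_iter):
        lo = idx <= t
        n_lo, n_hi = h[lo].sum(), h[~lo].sum()
        if n_lo == 0 or n_hi == 0:
            break
        mu_lo = max(float((idx[lo] * h[lo]).sum()) / n_lo, 1e-9)
        mu_hi = max(float((idx[~lo] * h[~lo]).sum()) / n_hi, 1e-9)
        if abs(np.log(mu_hi) - np.log(mu_lo)) < 1e-12:
            break
        t_new = (mu_hi - mu_lo) / (np.log(mu_hi) - np.log(mu_lo))
        if abs(t_new - t) < 0.5:
            return t_new
        t = t_new
    return t


def isodata_intermeans_scan(h: np.ndarray) -> int:
    """Scan for the first split where the intermean falls behind the split."""
    n = len(h)
    nz = np.nonzero(h)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    if lo >= hi:
        return n // 2
    result = float(lo)
    for m in range(lo, hi):
        s1 = float(sum(i * h[i] for i in range(lo, m + 1)))
        s2 = float(h[lo : m + 1].sum())
        s3 = float(sum(i * h[i] for i in range(m + 1, hi + 1)))
        s4 = float(h[m + 1 : hi + 1].sum())
        result = (s1 / s2 + s3 / s4) / 2.0 if s2 > 0 and s4 > 0 else float(m)
        if not (m + 2 <= result and m + 1 < hi - 1):
            return int(round(result))
    return int(round(result))


def triangle_scan(h: np.ndarray) -> int:
    """Geometric triangle threshold via explicit perpendicular distances."""
    data = h.astype(float).copy()
    n = len(data)
    nz = np.nonzero(data)[0]
    mn = max(int(nz[0]) - 1, 0)
    mx2 = min(int(nz[-1]) + 1, n - 1)
    peak = int(np.argmax(data))
    inverted = (peak - mn) < (mx2 - peak)
    if inverted:
        data = data[::-1]
        mn, mx2 = n - 1 - mx2, n - 1 - mn
        peak = n - 1 - peak
    if mn == peak:
        split = mn
    else:
        dx, dy = float(peak - mn), float(data[peak])
        length = np.hypot(dx, dy)
        best, split = 0.0, mn
        for i in range(mn + 1, peak + 1):
            cross = dx * (data[i] - data[mn]) - dy * (i - mn)
            dist = -cross / length
            if dist > best:
                best, split = dist, i
        split -= 1
    if inverted:
        split = n - 1 - split
    return int(split)


THRESHOLD_SCANS = {
    "default_isodata": isodata_intermeans_scan,
    "otsu": otsu_scan,
    "triangle": triangle_scan,
    "mean": mean_scan,
    "li": li_scan,
}


# ---------------------------------------------------------------------------
# matching and geometry
# ---------------------------------------------------------------------------


def max_matching_cardinality(ref: np.ndarray, comp: np.ndarray, radius: float) -> int:
    """Maximum bipartite matching size under a distance-radius constraint."""
    if len(ref) == 0 or len(comp) == 0:
        return 0
    d = np.sqrt(((ref[:, None, :] - comp[None, :, :]) ** 2).sum(-1))
    adj = csr_matrix((d <= radius).astype(np.int8))
    match = maximum_bipartite_matching(adj, perm_type="column")
    return int((match >= 0).sum())


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Ray-casting point-in-polygon test (single ring, no holes)."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


def disk_kernel_count(radius_px: float) -> int:
    """Number of integer offsets within the radius, counted one by one."""
    r = int(np.floor(radius_px))
    count = 0
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di * di + dj * dj <= radius_px * radius_px:
                count += 1
    return count


def hex_lattice_count_in_square(side: float, radius: float) -> int:
    """Circles retained on the bbox-anchored hex lattice inside a square."""
    count = 0
    j = 0
    row_pitch = radius * np.sqrt(3)
    while True:
        y = radius + j * row_pitch
        if y > side - radius:
            break
        offset = radius if j % 2 else 0.0
        i = 0
        while True:
            x = radius + offset + 2 * radius * i
            if x > side - radius:
                break
            count += 1
            i += 1
        j += 1
    return count
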