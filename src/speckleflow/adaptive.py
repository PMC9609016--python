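"""Adaptive analysis windows: reference images, selection masks, awK/sawK.

Adaptive contrast computation replaces the fixed d x d analysis window
with a per-pixel subset of it, chosen so that only pixels from the same
statistical population as the analyzed pixel enter the sigma/mu estimate.
Two selection strategies are implemented:

awK (adaptive-window contrast)
    The contrast image is grouped into intensity clusters (k-means on the
    1-D contrast values, k=3 by default: vessel, transition, static).
    For each pixel p, a region-growing pass inside the d x d window keeps
    the pixels connected to p that share p's cluster label.

sawK (spatially adaptive windowing contrast)
    The reference is an SLIC-style superpixel clustering of the contrast
    image: k centers seeded on a regular grid, nudged to the lowest
    gradient in a 3x3 neighbourhood, then iterated assignment/update
    with the combined distance D = ds + (M/S) * dc, where ds is the
    contrast-value difference and dc the Euclidean coordinate distance.
    Pixel selection then applies a three-way minimum-distance rule: a
    candidate pixel enters the window of p iff its combined distance to
    p is no larger than both its distance to its own cluster center and
    to the nearest other center.

Both produce, alongside the contrast image, a size map Zp = |Spd| giving
the number of selected pixels per analysis window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceImage",
    "SlicParams",
    "reference_awk",
    "reference_sawk",
    "combined_distance",
    "selection_mask_awk",
    "selection_mask_sawk",
    "selection_masks_awk",
    "selection_masks_sawk",
    "adaptive_contrast",
]


@dataclass
class ReferenceImage:
    """Cluster-label map guiding per-pixel selection.

    ``centers`` is an (k, 3) array of (row, col, contrast value) cluster
    centers for sawK references and ``None`` for awK (intensity-only)
    references.  ``weight`` stores the M/S distance weight the centers
    were fit with, so selection uses the same metric.
    """

    labels: np.ndarray
    centers: np.ndarray | None = None
    weight: float | None = None
    source: str = ""

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass(frozen=True)
class SlicParams:
    """SLIC-style clustering parameters.

    k is the number of centers; compactness M weighs coordinate distance
    against contrast difference through w = M/S with grid spacing
    S = sqrt(N/k) (N image pixels).
    """

    k: int = 64
    compactness: float = 0.1
    max_iter: int = 10
    tol: float = 0.0  # extra movement tolerance; 0 = iterate to stable labels

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.compactness <= 0:
            raise ValueError("compactness must be > 0")


def _order_labels_by_mean(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster 0 has the lowest mean value (most dynamic)."""
    uniq = np.unique(labels)
    means = ndimage.mean(values, labels=labels, index=uniq)
    order = np.argsort(means, kind="stable")
    remap = np.empty(uniq.max() + 1, dtype=np.int64)
    remap[uniq[order]] = np.arange(len(uniq))
    return remap[labels]


def reference_awk(
    ci: np.ndarray, n_clusters: int = 3, seed: int = 0
) -> ReferenceImage:
    """Intensity-only reference: 1-D k-means over the contrast values.

    Three clusters by default — vessel, transition region, static tissue.
    Labels are ordered by ascending cluster-mean contrast, so label 0 is
    reproducibly the most dynamic group.
    """
    from sklearn.cluster import KMeans

    ci = np.asarray(ci, dtype=np.float64)
    vals = ci.reshape(-1, 1)
    n_distinct = len(np.unique(vals))
    if n_distinct < n_clusters:
        warnings.warn(
            f"only {n_distinct} distinct contrast values for "
            f"{n_clusters} clusters; labels are degenerate",
            stacklevel=2,
        )
        _, labels = np.unique(vals, return_inverse=True)
        labels = labels.reshape(ci.shape)
        return ReferenceImage(labels=labels, source="awK")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(vals).reshape(ci.shape)
    return ReferenceImage(labels=_order_labels_by_mean(ci, labels), source="awK")


def combined_distance(ref_a, ref_b, pos_a, pos_b, M: float, S: float) -> float:
    """SLIC combined distance D = ds + (M/S) * dc.

    ds = |contrast difference|, dc = Euclidean coordinate distance.
    """
    if S <= 0:
        raise ValueError("grid spacing S must be > 0")
    ds = abs(float(ref_a) - float(ref_b))
    dc = float(np.hypot(pos_a[0] - pos_b[0], pos_a[1] - pos_b[1]))
    return ds + (M / S) * dc


def _seed_centers(h: int, w: int, k: int) -> np.ndarray:
    """Regular-grid seeding: ~sqrt(k * w/h) x ~sqrt(k * h/w) lattice."""
    # choose grid dimensions whose product is >= k, as square as possible
    ny = max(int(round(np.sqrt(k * h / w))), 1)
    nx = max(int(np.ceil(k / ny)), 1)
    ys = (np.arange(ny) + 0.5) * h / ny
    xs = (np.arange(nx) + 0.5) * w / nx
    pts = np.array([(y, x) for y in ys for x in xs])
    return pts[:k]


def _gradient_magnitude(ci: np.ndarray) -> np.ndarray:
    """Squared intensity difference to the four neighbours (reflect
    borders).  Unlike a central difference this is nonzero on a
    single-pixel spike, which the seed perturbation must avoid."""
    p = np.pad(ci, 1, mode="reflect")
    c = p[1:-1, 1:-1]
    g = np.zeros_like(c)
    for sl in (p[:-2, 1:-1], p[2:, 1:-1], p[1:-1, :-2], p[1:-1, 2:]):
        g += (sl - c) ** 2
    return g


def initial_centers(ci: np.ndarray, k: int) -> np.ndarray:
    """Regular-grid seeds perturbed to the lowest gradient in 3x3.

    Returns the (k, 3) array of (row, col, contrast) centers the
    clustering starts from; a center moves only on a strict gradient
    decrease, so seeds on a flat image stay on the lattice.
    """
    ci = np.asarray(ci, dtype=np.float64)
    h, w = ci.shape
    grad = _gradient_magnitude(ci)
    centers = np.empty((k, 3))
    for idx, (cy, cx) in enumerate(_seed_centers(h, w, k)):
        iy = min(max(int(round(cy)), 0), h - 1)
        ix = min(max(int(round(cx)), 0), w - 1)
        best = (iy, ix)
        best_g = grad[iy, ix]
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                y, x = iy + dy, ix + dx
                if 0 <= y < h and 0 <= x < w and grad[y, x] < best_g:
                    best, best_g = (y, x), grad[y, x]
        centers[idx] = (best[0], best[1], ci[best])
    return centers


def reference_sawk(
    ci: np.ndarray, params: SlicParams | None = None, seed: int = 0
) -> ReferenceImage:
    """SLIC-style superpixel reference over a contrast image.

    Centers are seeded at regular intervals, moved to the lowest-gradient
    position of their 3x3 neighbourhood, then assignment (pixels within a
    2S x 2S search region, combined distance D) and center update (cluster
    means) alternate until the labels stop changing or ``max_iter`` is
    reached.  Pixels left unassigned are attached to the nearest center
    by D.  The procedure is deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    params = params or SlicParams()
    ci = np.asarray(ci, dtype=np.float64)
    h, w = ci.shape
    n = h * w
    k = params.k
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pixels N={n}")
    S = float(np.sqrt(n / k))
    wgt = params.compactness / S

    centers = initial_centers(ci, k)  # row, col, value

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    labels = np.full((h, w), -1, dtype=np.int64)
    half = int(np.ceil(2 * S))
    for _ in range(params.max_iter):
        best_d = np.full((h, w), np.inf)
        new_labels = np.full((h, w), -1, dtype=np.int64)
        for c in range(k):
            cy, cx, cv = centers[c]
            y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
            x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
            ds = np.abs(ci[y0:y1, x0:x1] - cv)
            dc = np.hypot(rows[y0:y1] - cy, cols[:, x0:x1] - cx)
            d = ds + wgt * dc
            sel = d < best_d[y0:y1, x0:x1]
            best_d[y0:y1, x0:x1][sel] = d[sel]
            new_labels[y0:y1, x0:x1][sel] = c
        # attach any pixel outside every search region to the nearest center
        orphan = new_labels < 0
        if orphan.any():
            oy, ox = np.nonzero(orphan)
            d_all = (
                np.abs(ci[oy, ox][:, None] - centers[None, :, 2])
                + wgt
                * np.hypot(
                    oy[:, None] - centers[None, :, 0],
                    ox[:, None] - centers[None, :, 1],
                )
            )
            new_labels[oy, ox] = np.argmin(d_all, axis=1)
        changed = not np.array_equal(new_labels, labels)
        labels = new_labels
        # update centers to cluster means (position and value)
        for c in range(k):
            m = labels == c
            if m.any():
                centers[c] = (
                    rows.repeat(w, 1)[m].mean(),
                    cols.repeat(h, 0)[m].mean(),
                    ci[m].mean(),
                )
        if not changed:
            break
    return ReferenceImage(labels=labels, centers=centers, weight=wgt, source="sawK")


# ---------------------------------------------------------------------------
# Selection masks
# ---------------------------------------------------------------------------

_STRUCT_8 = np.zeros((1, 1, 3, 3), dtype=bool)
_STRUCT_8[0, 0] = True


def _label_windows(labels: np.ndarray, d: int) -> np.ndarray:
    r = (d - 1) // 2
    return sliding_window_view(np.pad(labels, r, mode="reflect"), (d, d))


def selection_masks_awk(ref: ReferenceImage, d: int) -> np.ndarray:
    """All awK selection masks at once: (H, W, d, d) boolean array.

    For each pixel p, marks the pixels of the d x d window (reflect
    padding at the borders) that are 8-connected to p through pixels
    sharing p's label — region growing seeded at p, as constrained
    morphological reconstruction over the stacked windows.
    """
    if d % 2 == 0 or d < 1:
        raise ValueError("window size d must be odd")
    labels = np.asarray(ref.labels)
    h, w = labels.shape
    r = (d - 1) // 2
    win = _label_windows(labels, d)
    same = win == labels[:, :, None, None]
    seed = np.zeros_like(same)
    seed[:, :, r, r] = True
    return ndimage.binary_propagation(seed, structure=_STRUCT_8, mask=same)


def selection_mask_awk(ref: ReferenceImage, p: tuple[int, int], d: int) -> np.ndarray:
    """awK selection mask (d x d) for the single pixel ``p``."""
    masks = selection_masks_awk(ref, d)
    return masks[p[0], p[1]]


def _pixel_center_distances(
    ci: np.ndarray, ref: ReferenceImage
) -> tuple[np.ndarray, np.ndarray]:
    """(d_own, d_other): combined distance of every pixel to its own
    cluster center and to the nearest other cluster center."""
    if ref.centers is None or ref.weight is None:
        raise ValueError("sawK selection requires a reference with cluster centers")
    labels = ref.labels
    centers = np.asarray(ref.centers, dtype=np.float64)
    wgt = float(ref.weight)
    h, w = labels.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    k = len(centers)
    d_all = np.empty((h, w, k))
    for c in range(k):
        cy, cx, cv = centers[c]
        d_all[:, :, c] = np.abs(ci - cv) + wgt * np.hypot(rows - cy, cols - cx)
    own = labels
    d_own = np.take_along_axis(d_all, own[:, :, None], axis=2)[:, :, 0]
    d_masked = d_all.copy()
    np.put_along_axis(d_masked, own[:, :, None], np.inf, axis=2)
    d_other = d_masked.min(axis=2)
    return d_own, d_other


def _window_offsets(d: int) -> np.ndarray:
    r = (d - 1) // 2
    off = np.arange(-r, r + 1, dtype=np.float64)
    return np.hypot(off[:, None], off[None, :])  # (d, d) Euclidean offsets


def selection_masks_sawk(
    ci: np.ndarray,
    ref: ReferenceImage,
    d: int,
    center_rule: str = "own-plus-nearest-other",
) -> np.ndarray:
    """All sawK selection masks at once: (H, W, d, d) boolean array.

    A candidate pixel pp in the window of p is included iff its combined
    distance to p is the minimum of three distances: to p, to pp's own
    cluster center, and to the nearest other cluster center (ties
    include, favouring sample size).  ``center_rule="two-nearest"``
    instead compares against the two nearest centers regardless of
    assignment.  The anchor pixel is always included.
    """
    if d % 2 == 0 or d < 1:
        raise ValueError("window size d must be odd")
    if center_rule not in ("own-plus-nearest-other", "two-nearest"):
        raise ValueError(f"unknown center_rule {center_rule!r}")
    ci = np.asarray(ci, dtype=np.float64)
    d_own, d_other = _pixel_center_distances(ci, ref)
    # Both readings reduce to the same threshold: min(own, nearest-other)
    # is the nearest center overall, which is also the min of the two
    # nearest centers regardless of assignment.
    thresh = np.minimum(d_own, d_other)
    r = (d - 1) // 2
    wgt = float(ref.weight)
    ci_win = sliding_window_view(np.pad(ci, r, mode="reflect"), (d, d))
    thr_win = sliding_window_view(np.pad(thresh, r, mode="reflect"), (d, d))
    d_to_p = np.abs(ci_win - ci[:, :, None, None]) + wgt * _window_offsets(d)
    masks = d_to_p <= thr_win
    masks[:, :, r, r] = True
    return masks


def selection_mask_sawk(
    ci: np.ndarray,
    ref: ReferenceImage,
    p: tuple[int, int],
    d: int,
    center_rule: str = "own-plus-nearest-other",
) -> np.ndarray:
    """sawK selection mask (d x d) for the single pixel ``p``."""
    return selection_masks_sawk(ci, ref, d, center_rule)[p[0], p[1]]


# ---------------------------------------------------------------------------
# Adaptive contrast
# ---------------------------------------------------------------------------


def masked_window_stats(
    frame: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, population std, count) over the selected window pixels."""
    d = masks.shape[-1]
    r = (d - 1) // 2
    frame = np.asarray(frame, dtype=np.float64)
    win = sliding_window_view(np.pad(frame, r, mode="reflect"), (d, d))
    n = masks.sum(axis=(-2, -1)).astype(np.float64)
    s = np.where(masks, win, 0.0).sum(axis=(-2, -1))
    mu = s / n
    dev = np.where(masks, win - mu[..., None, None], 0.0)
    var = (dev * dev).sum(axis=(-2, -1)) / n
    return mu, np.sqrt(var), n.astype(np.int64)


def adaptive_contrast(
    frame: np.ndarray,
    ref: ReferenceImage,
    method: str = "awK",
    d_max: int = 11,
    *,
    ci: np.ndarray | None = None,
    center_rule: str = "own-plus-nearest-other",
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive-window contrast (awK or sawK) plus its size map.

    Per pixel, population sigma/mu over the pixels its selection mask
    marks inside the d_max x d_max window.  Singleton masks (no variance
    estimable) and zero-mean windows yield K = 0 and are counted in the
    log.  Returns ``(contrast image, size map Zp)``.

    For ``method="sawK"``, ``ci`` must supply the contrast image the
    reference was built from (the selection rule measures contrast
    distances, which the label map alone does not carry).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != ref.labels.shape:
        raise ValueError("frame and reference image shapes differ")
    if method == "awK":
        masks = selection_masks_awk(ref, d_max)
    elif method == "sawK":
        if ci is None:
            raise ValueError("sawK adaptive contrast requires the source ci")
        masks = selection_masks_sawk(ci, ref, d_max, center_rule)
    else:
        raise ValueError(f"unknown adaptive method {method!r}")
    mu, std, n = masked_window_stats(frame, masks)
    singleton = n == 1
    n_single = int(singleton.sum())
    if n_single:
        logger.info(
            "adaptive_contrast(%s): %d singleton masks set to K=0", method, n_single
        )
    zero = mu == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(singleton | zero, 0.0, std / np.where(zero, 1.0, mu))
    if clip:
        k = np.clip(k, 0.0, 1.0)
    return k, n
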