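"""Segmentation-guided contrast recalculation.

Once a vessel/tissue segmentation exists it can serve as the reference
image for a second, sharper contrast computation: each pixel's analysis
window is restricted to the window pixels on its own side of the
segmentation boundary, so vessel and tissue statistics never mix.

A raw segmentation first needs cleanup, since isolated pixels would
produce one-pixel analysis windows with no estimable statistics:

1. morphological closing with a disk of radius 1 (small enough not to
   thicken the vessel periphery);
2. an area filter removing foreground objects below 25 pixels — fewer
   samples than a 5x5 window provides;
3. a reconnection sweep: a tissue pixel that sees at least one vessel
   pixel along each of the four axis directions (up, down, left, right,
   anywhere within the search radius) is relabeled vessel, filling holes
   inside vessels.  The sweep is iterated to its fixed point, so it is
   monotone (vessel pixels only accumulate) and idempotent.

Recalculated contrasts at several window sizes combine into the
multi-scale image msrK: per pixel the minimum over scales inside vessels
(preserving the low contrast at the vessel center) and the maximum over
scales in tissue (preserving noise suppression outside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .adaptive import ReferenceImage, masked_window_stats, selection_masks_awk

logger = logging.getLogger(__name__)

__all__ = [
    "CleanSegmentation",
    "MultiScaleContrast",
    "clean_segmentation",
    "recalculate_contrast",
    "multiscale_recalc",
]


@dataclass
class CleanSegmentation:
    """Cleaned binary vessel mask plus an audit of what changed."""

    mask: np.ndarray
    audit: dict[str, int] = field(default_factory=dict)


def _reconnect_once(mask: np.ndarray, radius: int | None) -> np.ndarray:
    """One reconnection sweep: relabel tissue pixels flanked by vessel
    pixels in all four axis directions (within ``radius``, or anywhere
    in the row/column if ``radius`` is None)."""
    m = mask
    if radius is None:
        up = np.maximum.accumulate(m, axis=0)
        down = np.maximum.accumulate(m[::-1], axis=0)[::-1]
        left = np.maximum.accumulate(m, axis=1)
        right = np.maximum.accumulate(m[:, ::-1], axis=1)[:, ::-1]
        # "sees a vessel pixel strictly in that direction": shift by one
        has_up = np.zeros_like(m)
        has_up[1:] = up[:-1]
        has_down = np.zeros_like(m)
        has_down[:-1] = down[1:]
        has_left = np.zeros_like(m)
        has_left[:, 1:] = left[:, :-1]
        has_right = np.zeros_like(m)
        has_right[:, :-1] = right[:, 1:]
    else:
        h, w = m.shape
        has_up = np.zeros_like(m)
        has_down = np.zeros_like(m)
        has_left = np.zeros_like(m)
        has_right = np.zeros_like(m)
        for s in range(1, radius + 1):
            has_up[s:] |= m[:-s]
            has_down[:-s] |= m[s:]
            has_left[:, s:] |= m[:, :-s]
            has_right[:, :-s] |= m[:, s:]
    return m | (has_up & has_down & has_left & has_right)


def clean_segmentation(
    seg: np.ndarray,
    disk_radius: int = 1,
    min_area: int = 25,
    reconnect_radius: int | None = None,
) -> CleanSegmentation:
    """Morphological cleanup pipeline: closing, area filter, reconnection.

    ``reconnect_radius=None`` searches the whole row/column for flanking
    vessel pixels (an adjacent-only search could never fill multi-pixel
    holes); pass a radius to bound the search.  Reconnection only turns
    tissue into vessel and is iterated to convergence, so applying the
    pipeline to its own output changes nothing.
    """
    from skimage.morphology import closing, disk, remove_small_objects

    seg = np.asarray(seg)
    if not np.isin(seg, (0, 1)).all():
        raise ValueError("segmentation mask must be binary")
    seg = seg.astype(bool)

    closed = closing(seg, disk(disk_radius))
    n_closed = int((closed ^ seg).sum())
    # 8-connected foreground objects with area < min_area are discarded
    filtered = remove_small_objects(closed, max_size=min_area - 1, connectivity=2)
    n_filtered = int((closed ^ filtered).sum())
    recon = filtered
    while True:
        grown = _reconnect_once(recon, reconnect_radius)
        if np.array_equal(grown, recon):
            break
        recon = grown
    n_recon = int((recon ^ filtered).sum())
    audit = {
        "closing_changed": n_closed,
        "area_filter_removed": n_filtered,
        "reconnection_added": n_recon,
    }
    logger.info("clean_segmentation audit: %s", audit)
    return CleanSegmentation(mask=recon, audit=audit)


def recalculate_contrast(
    frame: np.ndarray,
    clean: CleanSegmentation | np.ndarray,
    d: int = 11,
    *,
    clip: bool = True,
) -> np.ndarray:
    """Contrast with the segmentation as the selection reference (rK).

    For each pixel, the analysis window keeps only the window pixels
    connected to it through pixels with the same vessel/tissue label —
    the adaptive-window criterion with the cleaned segmentation standing
    in for the clustered reference image.  Singleton selections and
    zero-mean windows give K = 0.
    """
    mask = clean.mask if isinstance(clean, CleanSegmentation) else np.asarray(clean)
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != mask.shape:
        raise ValueError("frame and segmentation shapes differ")
    ref = ReferenceImage(labels=mask.astype(np.int64), source="segmentation")
    masks = selection_masks_awk(ref, d)
    mu, std, n = masked_window_stats(frame, masks)
    singleton = n == 1
    zero = mu == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(singleton | zero, 0.0, std / np.where(zero, 1.0, mu))
    return np.clip(k, 0.0, 1.0) if clip else k


@dataclass
class MultiScaleContrast:
    """Per-scale recalculated contrasts and their min/max combination."""

    scales: list[int]
    per_scale: dict[int, np.ndarray]
    msrk: np.ndarray


def multiscale_recalc(
    frame: np.ndarray,
    clean: CleanSegmentation | np.ndarray,
    scales: tuple[int, ...] = (5, 7, 9, 11),
    *,
    vessel_low: bool = True,
    clip: bool = True,
) -> MultiScaleContrast:
    """Multi-scale recalculated contrast msrK.

    Computes rK at each window size in ``scales`` (odd, ascending) and
    combines them per pixel: the minimum over scales at vessel pixels
    and the maximum at tissue pixels (``vessel_low=True``, keeping the
    vessel center dark and the tissue clean).  ``vessel_low=False``
    swaps the branches for the opposite mask encoding.
    """
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(s % 2 == 0 for s in scales):
        raise ValueError("all scales must be odd")
    if list(scales) != sorted(scales):
        raise ValueError("scales must be ascending")
    mask = clean.mask if isinstance(clean, CleanSegmentation) else np.asarray(clean)
    mask = mask.astype(bool)
    per_scale = {
        int(s): recalculate_contrast(frame, mask, int(s), clip=clip) for s in scales
    }
    stackk = np.stack(list(per_scale.values()), axis=0)
    lo = stackk.min(axis=0)
    hi = stackk.max(axis=0)
    vessel = mask if vessel_low else ~mask
    msrk = np.where(vessel, lo, hi)
    return MultiScaleContrast(scales=[int(s) for s in scales], per_scale=per_scale, msrk=msrk)
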