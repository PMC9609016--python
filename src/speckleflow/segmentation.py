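"""Per-pixel feature extraction, weighted k-NN segmentation, and evaluation.

Each pixel of a raw speckle frame becomes one observation: seven order
statistics (sum, max, min, mean, range, population std, Shannon entropy)
of the intensities inside its analysis window — the full d x d square
for traditional extraction, or the adaptively selected subset for
awK/sawK extraction — optionally augmented with the pixel's own contrast
value.  A distance-weighted k-nearest-neighbour classifier trained with
stratified 10-fold cross-validation separates vessel (1) from tissue (0)
pixels, and segmentations are scored with the Jaccard index, optionally
restricted to a band around the true vessel boundary (the "periphery")
where spatial-resolution differences actually show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "EvalReport",
    "window_features",
    "extract_features",
    "train_segmenter",
    "predictions_to_mask",
    "jaccard",
    "periphery_jaccard",
    "improvement_percent",
]

FEATURE_NAMES = ("sum", "max", "min", "mean", "range", "std", "entropy")
ENTROPY_BINS = 32


def _masked_entropy(
    win: np.ndarray, masks: np.ndarray, n: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Shannon entropy (base 2) of the selected intensities per window.

    Histogram over ``ENTROPY_BINS`` equal-width bins spanning the global
    frame range [lo, hi] — a fixed binning keeps entropies comparable
    across pixels with different selection sizes.
    """
    if hi == lo:
        return np.zeros(n.shape)
    # bin index per window pixel, then per-bin masked counts
    idx = np.clip(
        ((win - lo) * (ENTROPY_BINS / (hi - lo))).astype(np.int64),
        0,
        ENTROPY_BINS - 1,
    )
    n = np.maximum(n, 1)  # empty selections contribute zero entropy
    ent = np.zeros(n.shape)
    for b in range(ENTROPY_BINS):
        cnt = (masks & (idx == b)).sum(axis=(-2, -1))
        p = cnt / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        ent += term
    return ent


def window_features(frame: np.ndarray, masks: np.ndarray) -> dict[str, np.ndarray]:
    """The seven per-pixel statistics over the selected window pixels.

    ``masks`` is the (H, W, d, d) selection array (all-ones for
    traditional square-window extraction).  Singleton selections give
    range = std = entropy = 0 by construction.
    """
    frame = np.asarray(frame, dtype=np.float64)
    d = masks.shape[-1]
    r = (d - 1) // 2
    win = sliding_window_view(np.pad(frame, r, mode="reflect"), (d, d))
    n = masks.sum(axis=(-2, -1)).astype(np.float64)
    empty = n == 0
    n_safe = np.maximum(n, 1)
    total = np.where(masks, win, 0.0).sum(axis=(-2, -1))
    mean = total / n_safe
    mx = np.where(empty, 0.0, np.where(masks, win, -np.inf).max(axis=(-2, -1)))
    mn = np.where(empty, 0.0, np.where(masks, win, np.inf).min(axis=(-2, -1)))
    dev = np.where(masks, win - mean[..., None, None], 0.0)
    std = np.sqrt((dev * dev).sum(axis=(-2, -1)) / n_safe)
    ent = _masked_entropy(win, masks, n, float(frame.min()), float(frame.max()))
    return {
        "sum": total,
        "max": mx,
        "min": mn,
        "mean": mean,
        "range": mx - mn,
        "std": std,
        "entropy": ent,
    }


def _full_window_masks(shape: tuple[int, int], d: int) -> np.ndarray:
    return np.ones(shape + (d, d), dtype=bool)


def extract_features(
    frame: np.ndarray,
    masks: np.ndarray | None = None,
    d: int = 5,
    *,
    contrast_image: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    tag: str | None = None,
) -> pd.DataFrame:
    """Build the per-pixel feature table.

    Parameters
    ----------
    frame : ndarray
        Raw intensity frame the statistics are computed on.
    masks : ndarray, optional
        (H, W, d, d) selection masks from an adaptive provider; ``None``
        selects the full square window of size ``d`` (traditional
        extraction).
    contrast_image : ndarray, optional
        If given, the anchor pixel's contrast value is appended as an
        extra feature column ``k_anchor``.
    labels : ndarray, optional
        Ground-truth vessel mask; adds the class column ``label``.
    tag : str, optional
        Provenance tag stored in ``DataFrame.attrs["provider"]``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    traditional = masks is None
    if traditional:
        masks = _full_window_masks(frame.shape, d)
    feats = window_features(frame, masks)
    h, w = frame.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    data = {"row": rr.ravel(), "col": cc.ravel()}
    for name in FEATURE_NAMES:
        data[name] = feats[name].ravel()
    if contrast_image is not None:
        data["k_anchor"] = np.asarray(contrast_image, dtype=np.float64).ravel()
    if labels is not None:
        data["label"] = np.asarray(labels).astype(np.int64).ravel()
    table = pd.DataFrame(data)
    table.attrs["provider"] = tag or ("traditional" if traditional else "adaptive")
    return table


@dataclass
class EvalReport:
    """Cross-validated segmentation quality summary."""

    fold_ji: list[float]
    mean_ji: float
    confusion: dict[str, int]
    cv_predictions: np.ndarray = field(repr=False)
    periphery_ji: float | None = None
    improvement_pct: float | None = None

    def to_dict(self) -> dict:
        out = {
            "fold_ji": [float(j) for j in self.fold_ji],
            "mean_ji": float(self.mean_ji),
            "confusion": {k: int(v) for k, v in self.confusion.items()},
        }
        if self.periphery_ji is not None:
            out["periphery_ji"] = float(self.periphery_ji)
        if self.improvement_pct is not None:
            out["improvement_pct"] = float(self.improvement_pct)
        return out


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c not in ("row", "col", "label")]
    return table[cols].to_numpy(dtype=np.float64)


def train_segmenter(
    table: pd.DataFrame,
    k_neighbors: int = 10,
    folds: int = 10,
    seed: int = 0,
):
    """Distance-weighted k-NN with stratified cross-validation.

    Features are z-scored inside each training fold.  Per-fold Jaccard
    indices are computed on the held-out pixels; the returned model is
    refit on all rows for prediction.  ``EvalReport.cv_predictions``
    holds the out-of-fold label of every pixel, aligned with the table
    rows, so a cross-validated segmentation mask can be reassembled.

    Raises ``ValueError`` if the table lacks labels or only one class is
    present.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if "label" not in table.columns:
        raise ValueError("feature table has no label column")
    y = table["label"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both vessel and tissue pixels are required for training")
    X = _feature_matrix(table)

    def fresh_model():
        return make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(n_neighbors=k_neighbors, weights="distance"),
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_pred = np.empty_like(y)
    fold_ji = []
    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(X, y):
        m = fresh_model()
        m.fit(X[train_idx], y[train_idx])
        pred = m.predict(X[test_idx])
        cv_pred[test_idx] = pred
        truth = y[test_idx]
        t = int(np.sum((pred == 1) & (truth == 1)))
        f_p = int(np.sum((pred == 1) & (truth == 0)))
        f_n = int(np.sum((pred == 0) & (truth == 1)))
        t_n = int(np.sum((pred == 0) & (truth == 0)))
        tp, fp, fn, tn = tp + t, fp + f_p, fn + f_n, tn + t_n
        denom = t + f_p + f_n
        fold_ji.append(1.0 if denom == 0 else t / denom)
    model = fresh_model()
    model.fit(X, y)
    report = EvalReport(
        fold_ji=fold_ji,
        mean_ji=float(np.mean(fold_ji)),
        confusion={"TP": tp, "FP": fp, "FN": fn, "TN": tn},
        cv_predictions=cv_pred,
    )
    return model, report


def predictions_to_mask(
    table: pd.DataFrame, predictions: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Reassemble per-row predictions into an (H, W) binary mask."""
    mask = np.zeros(shape, dtype=bool)
    mask[table["row"].to_numpy(), table["col"].to_numpy()] = predictions.astype(bool)
    return mask


def jaccard(seg: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard index TP / (TP + FP + FN) between two binary masks.

    Both masks empty is perfect agreement (JI = 1).
    """
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    union = np.logical_or(seg, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(seg, gt).sum() / union)


def periphery_jaccard(
    seg: np.ndarray, gt: np.ndarray, band_radius_px: int = 5
) -> float:
    """Jaccard index restricted to a band around the vessel boundary.

    The band is dilation(gt, disk(r)) XOR erosion(gt, disk(r)): the
    pixels within ``band_radius_px`` of the true boundary, where
    segmentation methods actually differ.  Raises if the band is empty
    (no boundary, e.g. an all-tissue or all-vessel ground truth, or
    radius 0).
    """
    from skimage.morphology import dilation, disk, erosion

    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    if band_radius_px < 1:
        raise ValueError("band_radius_px must be >= 1 (empty band)")
    footprint = disk(band_radius_px)
    band = dilation(gt, footprint) ^ erosion(gt, footprint)
    if not band.any():
        raise ValueError("periphery band is empty: ground truth has no boundary")
    return jaccard(seg[band], gt[band])


def improvement_percent(ji_adaptive: float, ji_traditional: float) -> float:
    """Relative JI improvement of the adaptive method, in percent."""
    if ji_traditional <= 0:
        raise ValueError("baseline Jaccard index must be positive")
    return 100.0 * (ji_adaptive - ji_traditional) / ji_traditional
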