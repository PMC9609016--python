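"""Traditional speckle contrast estimators.

Laser speckle contrast imaging converts a raw speckle image (RSI) into a
contrast image K = sigma/mu computed over a local sample of pixels.  Low K
indicates motion blur (blood flow); K near 1 indicates static, fully
developed speckle.  This module implements the three traditional
estimators used throughout the field:

* spatial contrast ``sK`` — sigma/mu over a d x d window of one frame;
* temporal contrast ``tK`` — sigma/mu of one pixel along n frames;
* averaged spatial contrast ``asK`` — the per-pixel mean of sK over a
  stack of frames (the usual noise/spatial-resolution compromise).

All variances use the population divisor (d^2, resp. n), matching the
printed estimator definitions, not the unbiased n-1 form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "WindowConfig",
    "spatial_contrast",
    "temporal_contrast",
    "averaged_spatial_contrast",
    "normalize",
]


@dataclass(frozen=True)
class WindowConfig:
    """Analysis-window configuration for spatial contrast.

    Parameters
    ----------
    d : int
        Side of the square analysis window; must be odd and >= 3.
        5 is the standard spatial-resolution choice, 7 trades
        resolution for noise attenuation.
    border_mode : {"reflect", "valid"}
        ``reflect`` pads the frame so the output has the input shape;
        ``valid`` restricts the output to the interior
        (shape ``(H - d + 1, W - d + 1)``).
    """

    d: int = 5
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.d < 3 or self.d % 2 == 0:
            raise ValueError(f"window size d must be odd and >= 3, got {self.d}")
        if self.border_mode not in ("reflect", "valid"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")

    @property
    def radius(self) -> int:
        return (self.d - 1) // 2


def _window_view(frame: np.ndarray, d: int, border_mode: str) -> np.ndarray:
    """(H, W, d, d) view of all d x d windows, honouring the border mode."""
    if border_mode == "reflect":
        r = (d - 1) // 2
        frame = np.pad(frame, r, mode="reflect")
    return sliding_window_view(frame, (d, d))


def _sigma_mu_ratio(mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """K = sigma/mu with the zero-mean convention K = 0."""
    zero = mean == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("contrast: %d zero-mean windows set to K=0", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(zero, 0.0, std / np.where(zero, 1.0, mean))
    return k


def spatial_contrast(
    frame: np.ndarray, cfg: WindowConfig | None = None, *, clip: bool = True
) -> np.ndarray:
    """Spatial contrast sK: population sigma/mu over each d x d window.

    Parameters
    ----------
    frame : ndarray
        One nonnegative grayscale frame.
    cfg : WindowConfig
        Window size and border handling; defaults to d=5, reflect.
    clip : bool
        Clip the result to [0, 1] (the stated range of a contrast
        image).  Pass ``clip=False`` to obtain the raw estimator values
        for statistical work.

    Returns
    -------
    ndarray
        Contrast image, same shape as ``frame`` for reflect borders.
    """
    cfg = cfg or WindowConfig()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.any(frame < 0):
        raise ValueError("frame intensities must be nonnegative")
    # Two-pass moments on an explicit window view: no uniform-filter
    # cancellation error, so K matches direct summation to float precision
    # even for high-bit-depth integer frames.
    win = _window_view(frame, cfg.d, cfg.border_mode)
    mu = win.mean(axis=(-2, -1))
    std = np.sqrt(((win - mu[..., None, None]) ** 2).mean(axis=(-2, -1)))
    k = _sigma_mu_ratio(mu, std)
    return np.clip(k, 0.0, 1.0) if clip else k


def temporal_contrast(stack: np.ndarray, n: int, *, clip: bool = True) -> np.ndarray:
    """Temporal contrast tK: sigma/mu of each pixel along the first n frames.

    ``stack`` is (H, W, T); at least 15 frames are customary for a
    stable estimate, and n must satisfy 2 <= n <= T.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (H, W, T)")
    if n < 2:
        raise ValueError(f"temporal contrast needs n >= 2 frames, got {n}")
    if n > stack.shape[2]:
        raise ValueError(f"n={n} exceeds stack depth T={stack.shape[2]}")
    sub = stack[:, :, :n]
    mu = sub.mean(axis=2)
    std = sub.std(axis=2)  # population divisor n
    k = _sigma_mu_ratio(mu, std)
    return np.clip(k, 0.0, 1.0) if clip else k


def averaged_spatial_contrast(
    stack: np.ndarray,
    cfg: WindowConfig | None = None,
    n_frames: int = 15,
    *,
    clip: bool = True,
) -> np.ndarray:
    """Averaged spatial contrast asK: mean of per-frame sK over n_frames."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (H, W, T)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames > stack.shape[2]:
        raise ValueError(
            f"n_frames={n_frames} exceeds stack depth T={stack.shape[2]}"
        )
    acc = None
    for t in range(n_frames):
        k = spatial_contrast(stack[:, :, t], cfg, clip=False)
        acc = k if acc is None else acc + k
    out = acc / n_frames
    return np.clip(out, 0.0, 1.0) if clip else out


def normalize(
    image: np.ndarray, gmin: float = 0.0, gmax: float = 1.0
) -> np.ndarray:
    """Affine intensity stretch mapping [Imin, Imax] onto [gmin, gmax]."""
    if gmax <= gmin:
        raise ValueError(f"gmax must exceed gmin, got [{gmin}, {gmax}]")
    image = np.asarray(image, dtype=np.float64)
    imin, imax = image.min(), image.max()
    if imax == imin:
        raise ValueError("cannot normalize a constant image (Imax == Imin)")
    return (gmax - gmin) / (imax - imin) * (image - imin) + gmin
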