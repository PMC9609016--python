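"""Independent brute-force oracles used to pin down expected values.

Everything here is written as explicit loops or direct enumeration,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def reflect_pad_index(i: int, n: int) -> int:
    """Index into an array of length n under symmetric (reflect) padding."""
    period = 2 * n - 2 if n > 1 else 1
    i = i % period if i >= 0 else (-i) % period
    if i >= n:
        i = period - i
    return i


def spatial_contrast_loop(frame: np.ndarray, d: int) -> np.ndarray:
    """Per-pixel population sigma/mu over d x d windows, reflect borders."""
    h, w = frame.shape
    r = d // 2
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    vals.append(
                        frame[reflect_pad_index(y + dy, h), reflect_pad_index(x + dx, w)]
                    )
            mu = sum(vals) / len(vals)
            var = sum((v - mu) ** 2 for v in vals) / len(vals)
            out[y, x] = 0.0 if mu == 0 else math.sqrt(var) / mu
    return out


def temporal_contrast_loop(stack: np.ndarray, n: int) -> np.ndarray:
    h, w, _ = stack.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = [float(stack[y, x, t]) for t in range(n)]
            mu = sum(vals) / n
            var = sum((v - mu) ** 2 for v in vals) / n
            out[y, x] = 0.0 if mu == 0 else math.sqrt(var) / mu
    return out


def flood_fill_mask(labels: np.ndarray, p: tuple[int, int], d: int) -> np.ndarray:
    """Region-grow (8-connectivity) same-label pixels inside the d x d
    window centered at p, reflect borders; explicit BFS."""
    h, w = labels.shape
    r = d // 2
    win = np.empty((d, d), dtype=labels.dtype)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            win[dy + r, dx + r] = labels[
                reflect_pad_index(p[0] + dy, h), reflect_pad_index(p[1] + dx, w)
            ]
    target = win[r, r]
    mask = np.zeros((d, d), dtype=bool)
    stack = [(r, r)]
    mask[r, r] = True
    while stack:
        y, x = stack.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < d and 0 <= xx < d and not mask[yy, xx] and win[yy, xx] == target:
                    mask[yy, xx] = True
                    stack.append((yy, xx))
    return mask


def sawk_mask_loop(
    ci: np.ndarray,
    labels: np.ndarray,
    centers: np.ndarray,
    weight: float,
    p: tuple[int, int],
    d: int,
) -> np.ndarray:
    """Three-way minimum-distance selection, candidate by candidate.

    A window pixel pp is included iff D(pp, p) <= min over the distances
    from pp to its own cluster center and to the nearest other center,
    using D = |contrast diff| + weight * Euclidean coordinate distance.
    Reflect borders; the anchor is always included.
    """
    h, w = ci.shape
    r = d // 2
    mask = np.zeros((d, d), dtype=bool)
    py, px = p
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            qy = reflect_pad_index(py + dy, h)
            qx = reflect_pad_index(px + dx, w)
            d_to_p = abs(ci[qy, qx] - ci[py, px]) + weight * math.hypot(dy, dx)
            own = labels[qy, qx]
            d_own = math.inf
            d_other = math.inf
            for c, (cy, cx, cv) in enumerate(centers):
                dist = abs(ci[qy, qx] - cv) + weight * math.hypot(qy - cy, qx - cx)
                if c == own:
                    d_own = dist
                elif dist < d_other:
                    d_other = dist
            if d_to_p <= min(d_own, d_other):
                mask[dy + r, dx + r] = True
    mask[r, r] = True
    return mask


def window_feature_loop(frame: np.ndarray, p: tuple[int, int], d: int) -> dict:
    """The seven statistics over the full d x d window at p, reflect
    borders, 32-bin base-2 entropy over the frame's global range."""
    h, w = frame.shape
    r = d // 2
    vals = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            vals.append(
                float(frame[reflect_pad_index(p[0] + dy, h), reflect_pad_index(p[1] + dx, w)])
            )
    n = len(vals)
    mu = sum(vals) / n
    var = sum((v - mu) ** 2 for v in vals) / n
    lo, hi = float(frame.min()), float(frame.max())
    ent = 0.0
    if hi > lo:
        counts = [0] * 32
        for v in vals:
            b = int((v - lo) * 32 / (hi - lo))
            counts[min(max(b, 0), 31)] += 1
        for c in counts:
            if c:
                pr = c / n
                ent -= pr * math.log2(pr)
    return {
        "sum": sum(vals),
        "max": max(vals),
        "min": min(vals),
        "mean": mu,
        "range": max(vals) - min(vals),
        "std": math.sqrt(var),
        "entropy": ent,
    }


def bifurcated_pixel_count(h: int, w: int, vw: int) -> int:
    """Rasterize the Y-shape by explicit per-pixel inequalities."""
    split = h // 2
    c0 = w // 2 - vw // 2
    bw = max(vw // 2, 1)
    center = c0 + vw / 2.0
    count = 0
    for rr in range(h):
        for cc in range(w):
            if rr < split:
                if c0 <= cc < c0 + vw:
                    count += 1
            else:
                t = (rr - split + 1) / (h - split)
                inside = False
                for target in (w / 4.0, 3.0 * w / 4.0):
                    bc = center + t * (target - center)
                    lo = int(np.floor(bc - bw / 2.0))
                    if lo <= cc < lo + bw:
                        inside = True
                if inside:
                    count += 1
    return count


def mc_window_contrast_expectation(
    n_window: int,
    n_eff: int,
    bit_depth: int,
    mean_gray_fraction: float,
    n_mc: int,
    seed: int,
) -> tuple[float, float]:
    """(mean, std) of the population sigma/mu estimator over windows of
    ``n_window`` iid quantized speckle intensities — direct Monte Carlo,
    no package code."""
    rng = np.random.default_rng(seed)
    if n_eff == 1:
        x = rng.exponential(1.0, size=(n_mc, n_window))
    else:
        x = rng.gamma(n_eff, 1.0 / n_eff, size=(n_mc, n_window))
    vmax = 2**bit_depth - 1
    q = np.clip(np.rint(x * vmax * mean_gray_fraction), 0, vmax)
    mu = q.mean(axis=1)
    std = q.std(axis=1)
    k = std / mu
    return float(k.mean()), float(k.std())
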