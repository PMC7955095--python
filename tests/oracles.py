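"""Independent brute-force reference implementations.

Naive pixel loops, kept deliberately separate from the package: they are
the oracle that the vectorized pipeline stages must match bit-exactly on
small images. Slow by design — only use on <= 64x64 inputs.
"""

from __future__ import annotations

import math

import numpy as np


def mean_filter_loop(img: np.ndarray, radius: int) -> np.ndarray:
    """Square-neighborhood mean with replicated borders, rounded half-even."""
    h, w = img.shape
    out = np.zeros((h, w), np.uint16)
    n = (2 * radius + 1) ** 2
    for r in range(h):
        for c in range(w):
            s = 0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    s += int(img[rr, cc])
            out[r, c] = int(np.rint(s / n))
    return out


def contrast_stretch_loop(img: np.ndarray, saturation_pct: float) -> np.ndarray:
    """Min-max stretch to [0, 65535] clipping saturation_pct/2 per tail."""
    flat = sorted(int(v) for v in img.ravel())
    k = int(len(flat) * saturation_pct / 200.0)
    lo = flat[k]
    hi = flat[len(flat) - 1 - k]
    if hi <= lo:
        return img.copy()
    scale = 65535.0 / (hi - lo)
    out = np.zeros_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            v = np.rint((int(img[r, c]) - lo) * scale)
            out[r, c] = min(max(int(v), 0), 65535)
    return out


def _disc(radius: int) -> list[tuple[int, int]]:
    return [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]


def erode_disc_loop(img: np.ndarray, radius: int) -> np.ndarray:
    h, w = img.shape
    offsets = _disc(radius)
    out = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            m = None
            for dr, dc in offsets:
                v = img[min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)]
                m = v if m is None else min(m, v)
            out[r, c] = m
    return out


def dilate_disc_loop(img: np.ndarray, radius: int) -> np.ndarray:
    h, w = img.shape
    offsets = _disc(radius)
    out = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            m = None
            for dr, dc in offsets:
                v = img[min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)]
                m = v if m is None else max(m, v)
            out[r, c] = m
    return out


def tophat_disc_loop(img: np.ndarray, radius: int) -> np.ndarray:
    opened = dilate_disc_loop(erode_disc_loop(img.astype(np.int64), radius),
                              radius)
    return np.maximum(img.astype(np.int64) - opened, 0)


def triangle_threshold_loop(img: np.ndarray, n_bins: int = 256) -> int:
    """Zack triangle threshold by explicit geometry over all candidate bins."""
    shift = 16 - int(math.log2(n_bins))
    hist = [0] * n_bins
    for v in img.ravel():
        hist[int(v) >> shift] += 1
    nz = [i for i, h in enumerate(hist) if h > 0]
    if len(nz) < 2:
        raise ValueError("constant image")
    peak = max(range(n_bins), key=lambda i: (hist[i], -i))
    first, last = nz[0], nz[-1]
    tail = last if (last - peak) >= (peak - first) else first
    if tail == peak:
        tail = last if peak == first else first
    lo, hi = min(peak, tail), max(peak, tail)
    hp = float(hist[peak])
    best_b, best_d = min(peak, tail), -1.0
    for b in range(lo + 1, hi):
        d = abs(hp * (b - tail) - (peak - tail) * float(hist[b]))
        if d > best_d:
            best_d, best_b = d, b
    return best_b


def structure_tensor_fd(img: np.ndarray):
    """Central-difference structure tensor summed over the interior.

    A coarse independent check of the Gaussian-derivative tensor: on
    piecewise-smooth images both must agree on which axis dominates.
    """
    img = np.asarray(img, float)
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:, 1:-1] = (img[:, 2:] - img[:, :-2]) / 2.0
    gy[1:-1, :] = (img[2:, :] - img[:-2, :]) / 2.0
    inner = (slice(2, -2), slice(2, -2))
    return ((gx * gx)[inner].sum(), (gx * gy)[inner].sum(),
            (gy * gy)[inner].sum())
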