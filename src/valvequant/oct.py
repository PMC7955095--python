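"""OCT leaflet morphometry: resampling, refractive correction, composites,
area and region-wise thickness.

The raw OCT volume is anisotropic (axial vs lateral sampling are set by
different physics), and its axial axis records *optical* path length.
The processing chain therefore (1) converts the axial pitch to geometric
length by dividing by the tissue refractive index (1.33, water), (2)
resamples to an isotropic grid (2.255 µm default), (3) sums ten adjacent
cross-sections into a high-contrast composite, and (4) measures leaflet
area and per-region thickness on a segmentation mask with a three-region
grid along the base-to-tip axis (region 1 = tip, 3 = base).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .io_core import OCTVolume, mask_area_um2

logger = logging.getLogger("valvequant")

__all__ = [
    "MorphometryResult",
    "RegionGrid",
    "rescale_isotropic",
    "optical_to_geometric",
    "geometric_to_optical",
    "composite_cross_section",
    "measure_area",
    "measure_thickness",
    "assign_regions",
    "segment_leaflet",
]


@dataclass
class MorphometryResult:
    area_um2: float
    thickness_um: dict[int, float]
    source: str = "OCT"


@dataclass
class RegionGrid:
    """Three-region label map over a leaflet mask plus the base-to-tip axis."""

    labels: np.ndarray            # 0 outside mask, 1/2/3 inside
    axis: tuple[float, float]     # unit (row, col) vector pointing base -> tip
    tip_point: tuple[float, float]
    base_point: tuple[float, float]


def optical_to_geometric(vol: OCTVolume, n: float | None = None) -> OCTVolume:
    """Convert the axial pitch from optical path to geometric length.

    Geometric length = optical path / refractive index; lateral axes are
    untouched. Applying it to an already-geometric volume is rejected.
    """
    n = vol.refractive_index if n is None else float(n)
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if not vol.axial_is_optical:
        raise ValueError("axial pitch is already geometric")
    pitch = list(vol.pitch_um)
    pitch[vol.axial_axis] /= n
    return replace(vol, pitch_um=tuple(pitch), refractive_index=n,
                   axial_is_optical=False, isotropic=False)


def geometric_to_optical(vol: OCTVolume, n: float | None = None) -> OCTVolume:
    """Inverse of :func:`optical_to_geometric` (axial pitch times n)."""
    n = vol.refractive_index if n is None else float(n)
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if vol.axial_is_optical:
        raise ValueError("axial pitch is already optical")
    pitch = list(vol.pitch_um)
    pitch[vol.axial_axis] *= n
    return replace(vol, pitch_um=tuple(pitch), refractive_index=n,
                   axial_is_optical=True, isotropic=False)


def rescale_isotropic(vol: OCTVolume, target_pitch_um: float = 2.255) -> OCTVolume:
    """Trilinearly resample the volume to an isotropic voxel pitch.

    The per-axis sample count is rounded so the physical extent is
    preserved within one voxel. Axes already at the target pitch pass
    through unchanged.
    """
    if target_pitch_um <= 0:
        raise ValueError("target_pitch_um must be positive")
    old_shape = vol.voxels.shape
    new_shape = tuple(max(1, int(round(n * p / target_pitch_um)))
                      for n, p in zip(old_shape, vol.pitch_um))
    if new_shape == old_shape:
        voxels = vol.voxels.copy()
    else:
        voxels = resize(vol.voxels.astype(float), new_shape, order=1,
                        mode="edge", anti_aliasing=False, preserve_range=True)
    return replace(vol, voxels=voxels,
                   pitch_um=(target_pitch_um,) * 3, isotropic=True)


def composite_cross_section(vol: OCTVolume, index: int, window: int = 10,
                            axis: int = 1) -> np.ndarray:
    """Sum of ``window`` adjacent cross-sections around ``index``.

    Summation (not averaging) widens the dynamic range but raises the
    contrast and speckle SNR by roughly sqrt(window). The slab is
    [index - window//2, index - window//2 + window).
    """
    if axis == vol.axial_axis:
        raise ValueError("cross-sections must be taken along a lateral axis")
    n = vol.voxels.shape[axis]
    start = index - window // 2
    if window < 1 or start < 0 or start + window > n:
        raise ValueError(
            f"window {window} around index {index} exceeds axis of length {n}")
    slab = np.take(vol.voxels, np.arange(start, start + window), axis=axis)
    if np.issubdtype(slab.dtype, np.integer):
        return slab.sum(axis=axis, dtype=np.int64)
    return slab.sum(axis=axis, dtype=np.float64)


def measure_area(mask: np.ndarray, pitch_um: float) -> float:
    """Mask area in µm² (pixel count times pitch squared)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        logger.warning("measuring area of an empty mask")
        return 0.0
    return mask_area_um2(mask, pitch_um)


def assign_regions(mask: np.ndarray, tip_point: tuple[float, float],
                   base_point: tuple[float, float]) -> RegionGrid:
    """Split a leaflet mask into three equal-length regions along its axis.

    Mask pixels are projected onto the base-to-tip axis and the projected
    extent is cut into three equal intervals; the tip-most third is
    region 1 and the base third is region 3.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    tip = np.asarray(tip_point, float)
    base = np.asarray(base_point, float)
    axis = tip - base
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("tip and base points coincide")
    u = axis / norm

    rows, cols = np.nonzero(mask)
    s = (rows - base[0]) * u[0] + (cols - base[1]) * u[1]
    smin, smax = s.min(), s.max()
    extent = smax - smin
    labels = np.zeros(mask.shape, np.uint8)
    if extent == 0:
        labels[mask] = 1
    else:
        # fraction along base -> tip: 0 at base end, 1 at tip end
        f = (s - smin) / extent
        reg = np.where(f >= 2.0 / 3.0, 1, np.where(f >= 1.0 / 3.0, 2, 3))
        labels[rows, cols] = reg
    return RegionGrid(labels=labels, axis=(float(u[0]), float(u[1])),
                      tip_point=(float(tip[0]), float(tip[1])),
                      base_point=(float(base[0]), float(base[1])))


def _column_chords(mask_col: np.ndarray) -> int:
    """Length of the longest contiguous run of True pixels in a column."""
    if not mask_col.any():
        return 0
    padded = np.concatenate(([0], mask_col.view(np.uint8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    runs = edges[1::2] - edges[0::2]
    return int(runs.max())


def measure_thickness(mask: np.ndarray, grid: RegionGrid, pitch_um: float,
                      mode: str = "mean") -> dict[int, float]:
    """Per-region leaflet thickness from chords perpendicular to the axis.

    The mask (and region labels) are rotated so the base-to-tip axis is
    horizontal; each column is then one measurement ray, its chord the
    longest contiguous run of mask pixels. Per region the thickness is
    the mean chord (``mode="mean"``, default, robust to mask roughness)
    or the maximum chord (``mode="max"``). Regions without mask pixels
    yield NaN.
    """
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    mask = np.asarray(mask, bool)
    u_row, u_col = grid.axis
    angle_deg = math.degrees(math.atan2(u_row, u_col))
    if abs(angle_deg) > 1e-9:
        m = ndi.rotate(mask.astype(np.uint8), angle_deg, reshape=True,
                       order=0, prefilter=False).astype(bool)
        lab = ndi.rotate(grid.labels, angle_deg, reshape=True,
                         order=0, prefilter=False)
    else:
        m, lab = mask, grid.labels

    out: dict[int, float] = {}
    for region in (1, 2, 3):
        sel = m & (lab == region)
        cols = np.nonzero(sel.any(axis=0))[0]
        if cols.size == 0:
            logger.warning("region %d contains no mask pixels", region)
            out[region] = float("nan")
            continue
        chords = np.array([_column_chords(sel[:, c]) for c in cols], float)
        value = chords.mean() if mode == "mean" else chords.max()
        out[region] = float(value * pitch_um)
    return out


def segment_leaflet(image: np.ndarray) -> np.ndarray:
    """Otsu-based leaflet segmentation of a composite cross-section.

    Intended for phantoms and other high-contrast composites: Otsu
    threshold, small closing to bridge speckle dropouts, hole filling,
    and the largest connected component. Real-data masks come from manual
    segmentation and are supplied externally.
    """
    image = np.asarray(image, float)
    t = threshold_otsu(image)
    mask = image > t
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3), bool))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
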