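"""SHG collagen quantification with CARS-based cholesterol-crystal correction.

Per slice the chain is:

SHG:   mean filter (radius 1) -> min-max contrast stretch (0.4% saturated)
       -> fixed threshold (> 20,000) -> binary collagen+crystal mask
CARS:  mean filter -> contrast stretch -> top-hat background subtraction
       (disc radius 30 px) -> triangle (Zack) auto-threshold -> binary
       lipid mask (droplets + crystals)

Cholesterol crystals generate signal in both channels, so the pixelwise
product of the two binaries isolates them; their area fraction is
subtracted from the SHG fraction to obtain the collagen fraction. The
stack value is the arithmetic mean of the per-slice corrected fractions.

All stages are integer/float-deterministic and match a naive pixel-loop
implementation bit-exactly, so the whole chain is oracle-testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._morphology import tophat_disc
from .io_core import Channel, ImageStack, PipelineConfig

logger = logging.getLogger("valvequant")

__all__ = [
    "CollagenResult",
    "LipidResult",
    "mean_filter",
    "contrast_stretch",
    "preprocess_shg",
    "binarize_shg",
    "preprocess_cars",
    "triangle_threshold_bin",
    "binarize_cars",
    "crystal_corrected_fraction",
    "collagen_stack",
    "lipid_summary",
]


@dataclass
class CollagenResult:
    """Per-slice and stack-mean collagen area fractions (percent)."""

    per_slice_pct: list[float]
    mean_pct: float
    per_slice_crystal_pct: list[float]
    crystal_corrected: bool
    region: int | None = None
    config: PipelineConfig | None = None


@dataclass
class LipidResult:
    """Qualitative lipid summary from the CARS maximum intensity projection."""

    droplet_count: int
    droplet_area_pct: float
    crystal_area_pct: float
    max_intensity_projection: np.ndarray


def _check_u16(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D image")
    if image.dtype != np.uint16:
        raise TypeError(f"expected uint16 input, got {image.dtype}")
    return image


def mean_filter(image: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Neighborhood-mean smoothing over a (2r+1)^2 square, replicated borders.

    The sum is taken in exact integer arithmetic and divided with
    round-half-even, so the result is independent of summation order.
    """
    image = _check_u16(image)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    size = 2 * radius_px + 1
    total = ndi.uniform_filter(image.astype(np.int64) * (size * size),
                               size=size, mode="nearest")
    return np.rint(total / (size * size)).astype(np.uint16)


def contrast_stretch(image: np.ndarray, saturation_pct: float = 0.4) -> np.ndarray:
    """Linear min-max stretch to [0, 65535] with a saturated-pixel budget.

    ``saturation_pct`` is the total clipped fraction, split equally
    between the dark and bright tails (0.2% each at the default). A
    constant image is returned unchanged (the stretch is undefined).
    """
    image = _check_u16(image)
    if not 0.0 <= saturation_pct < 100.0:
        raise ValueError("saturation_pct must be in [0, 100)")
    flat = np.sort(image, axis=None)
    k = int(flat.size * saturation_pct / 200.0)
    lo = int(flat[k])
    hi = int(flat[flat.size - 1 - k])
    if hi <= lo:
        return image.copy()
    scale = 65535.0 / (hi - lo)
    out = np.rint((image.astype(np.int64) - lo) * scale)
    return np.clip(out, 0, 65535).astype(np.uint16)


def preprocess_shg(image: np.ndarray, radius_px: int = 1,
                   saturation_pct: float = 0.4) -> np.ndarray:
    """Smooth then contrast-stretch one SHG slice."""
    return contrast_stretch(mean_filter(image, radius_px), saturation_pct)


def binarize_shg(image: np.ndarray, threshold: int = 20000) -> np.ndarray:
    """Collagen(+crystal) mask: intensity strictly above the fixed threshold."""
    return np.asarray(image) > threshold


def preprocess_cars(image: np.ndarray, radius_px: int = 1,
                    saturation_pct: float = 0.4,
                    background_radius_px: int = 30) -> np.ndarray:
    """Smooth, stretch, then remove smooth background from one CARS slice.

    Background subtraction is a white top-hat with a flat disc of the
    given radius — the deterministic equivalent of a rolling-ball
    subtraction for structures smaller than the disc.
    """
    image = _check_u16(image)
    if 2 * background_radius_px + 1 > min(image.shape):
        raise ValueError("background radius does not fit into the image")
    stretched = contrast_stretch(mean_filter(image, radius_px), saturation_pct)
    return tophat_disc(stretched, background_radius_px).astype(np.uint16)


def triangle_threshold_bin(image: np.ndarray, n_bins: int = 256) -> int:
    """Triangle (Zack) threshold bin on a 256-bin histogram of 16-bit data.

    The histogram bin of each pixel is ``value // 256``. The threshold is
    the bin maximizing the distance between the histogram and the straight
    line from the histogram peak to the farther empty tail end. Applied to
    the histogram as-is: objects are assumed bright. Returns the threshold
    bin; pixels in strictly higher bins are foreground.

    Raises ``ValueError`` for a constant image (no threshold definable).
    """
    image = _check_u16(image)
    shift = 16 - int(np.log2(n_bins))
    bins = (image >> shift).ravel()
    hist = np.bincount(bins, minlength=n_bins).astype(np.int64)
    nz = np.nonzero(hist)[0]
    if nz.size < 2:
        raise ValueError("constant image: triangle threshold undefined")
    peak = int(np.argmax(hist))
    first, last = int(nz[0]), int(nz[-1])
    # farther tail end from the peak; ties go to the bright side
    tail = last if (last - peak) >= (peak - first) else first
    if tail == peak:  # two nonzero bins, peak at one end of range
        tail = last if peak == first else first
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    b = np.arange(lo + 1, hi)
    if b.size == 0:
        return min(peak, tail)
    hp = float(hist[peak])
    # unnormalized distance from (b, hist[b]) to the line (peak,hp)-(tail,0)
    d = np.abs(hp * (b - tail) - (peak - tail) * hist[b].astype(float))
    best = int(b[np.argmax(d)])
    return best


def binarize_cars(image: np.ndarray) -> np.ndarray:
    """Lipid mask from the triangle auto-threshold on a preprocessed CARS slice."""
    t = triangle_threshold_bin(image)
    return (np.asarray(image) >> 8) > t


def crystal_corrected_fraction(shg_mask: np.ndarray, cars_mask: np.ndarray,
                               ) -> tuple[float, float]:
    """Collagen and crystal area percentages from the two binary masks.

    The crystal fraction is the area that is both SHG- and CARS-active;
    the corrected collagen fraction is the SHG area that is not, so the
    identity corrected + crystal = raw SHG holds by construction.
    """
    shg_mask = np.asarray(shg_mask, bool)
    cars_mask = np.asarray(cars_mask, bool)
    if shg_mask.shape != cars_mask.shape:
        raise ValueError("mask geometry mismatch")
    n = shg_mask.size
    crystal = 100.0 * np.count_nonzero(shg_mask & cars_mask) / n
    corrected = 100.0 * np.count_nonzero(shg_mask & ~cars_mask) / n
    return corrected, crystal


def collagen_stack(shg: ImageStack, cars: ImageStack,
                   config: PipelineConfig | None = None,
                   region: int | None = None) -> CollagenResult:
    """Run the full collagen chain on an SHG/CARS stack pair.

    A CARS slice with no structure after preprocessing (constant image,
    triangle threshold undefined) is treated as "no lipid detected" and
    contributes no crystal correction.
    """
    config = config or PipelineConfig()
    if shg.channel != Channel.SHG:
        raise ValueError(f"first stack must be SHG, got {shg.channel}")
    if cars.channel != Channel.CARS:
        raise ValueError(f"second stack must be CARS, got {cars.channel}")
    if shg.shape != cars.shape:
        raise ValueError("SHG and CARS stacks differ in geometry")
    config.log()

    per_slice, per_crystal = [], []
    for shg_img, cars_img in zip(shg.pixels, cars.pixels):
        shg_bin = binarize_shg(
            preprocess_shg(shg_img, config.mean_filter_radius_px,
                           config.saturation_pct),
            config.shg_threshold)
        cars_pre = preprocess_cars(cars_img, config.mean_filter_radius_px,
                                   config.saturation_pct,
                                   config.background_radius_px)
        try:
            cars_bin = binarize_cars(cars_pre)
        except ValueError:
            cars_bin = np.zeros_like(shg_bin)  # no lipid detected
        corrected, crystal = crystal_corrected_fraction(shg_bin, cars_bin)
        per_slice.append(corrected)
        per_crystal.append(crystal)

    return CollagenResult(per_slice_pct=per_slice,
                          mean_pct=float(np.mean(per_slice)),
                          per_slice_crystal_pct=per_crystal,
                          crystal_corrected=True,
                          region=region, config=config)


def lipid_summary(cars: ImageStack, shg: ImageStack,
                  config: PipelineConfig | None = None) -> LipidResult:
    """Qualitative lipid quantification on the CARS maximum intensity projection.

    CARS-positive connected components (8-connectivity) are classified as
    cholesterol crystals when at least half of their pixels are also
    SHG-active, otherwise as lipid droplets.
    """
    config = config or PipelineConfig()
    if cars.shape != shg.shape:
        raise ValueError("stacks differ in geometry")
    mip_cars = cars.pixels.max(axis=0)
    mip_shg = shg.pixels.max(axis=0)

    cars_pre = preprocess_cars(mip_cars, config.mean_filter_radius_px,
                               config.saturation_pct,
                               config.background_radius_px)
    try:
        cars_bin = binarize_cars(cars_pre)
    except ValueError:
        return LipidResult(0, 0.0, 0.0, mip_cars)
    shg_bin = binarize_shg(
        preprocess_shg(mip_shg, config.mean_filter_radius_px,
                       config.saturation_pct),
        config.shg_threshold)

    labels, n_comp = ndi.label(cars_bin, structure=np.ones((3, 3), int))
    droplet_px = crystal_px = 0
    droplet_count = 0
    for i in range(1, n_comp + 1):
        comp = labels == i
        size = int(comp.sum())
        overlap = int(np.count_nonzero(comp & shg_bin))
        if overlap * 2 >= size:
            crystal_px += size
        else:
            droplet_px += size
            droplet_count += 1
    total = cars_bin.size
    return LipidResult(droplet_count=droplet_count,
                       droplet_area_pct=100.0 * droplet_px / total,
                       crystal_area_pct=100.0 * crystal_px / total,
                       max_intensity_projection=mip_cars)
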