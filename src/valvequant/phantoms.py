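"""Synthetic SHG/CARS/OCT/histology phantoms with exact ground truth.

The generators stand in for the animal data (none was deposited): they
emulate the image features the analysis chain exploits — a mesh of
oriented collagen fibers visible in SHG, lipid droplets visible only in
CARS, cholesterol crystals bright in *both* channels (the property the
crystal correction relies on), a curved leaflet band inside a speckled
OCT volume, and red-stained collagen on a pale counterstained background
for histology. Truth masks are recorded before noise, so every reported
fraction equals a pixel count divided by the image size exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .io_core import Channel, ImageStack, OCTVolume
from .histology import StainMatrix, default_psr_stains, od_to_rgb

__all__ = [
    "MPMPhantomSpec",
    "OCTPhantomSpec",
    "PhantomTruth",
    "generate_mpm_phantom",
    "generate_oct_phantom",
    "generate_histo_phantom",
]


@dataclass
class PhantomTruth:
    """Ground truth for a synthetic image; unused fields stay None."""

    collagen_fraction_pct: float | None = None
    crystal_fraction_pct: float | None = None
    droplet_count: int | None = None
    kappa: float | None = None
    mean_angle_deg: float | None = None
    fiber_masks: np.ndarray | None = None
    crystal_masks: np.ndarray | None = None
    droplet_masks: np.ndarray | None = None
    fiber_angles_deg: list | None = None
    thickness_um: dict | None = None
    area_um2: float | None = None
    psr_mask: np.ndarray | None = None
    psr_fraction_pct: float | None = None


@dataclass
class MPMPhantomSpec:
    """Recipe for a paired SHG/CARS stack.

    Defaults mimic the reference acquisition geometry (16-bit, 0.28 µm
    pixels, 14 slices per stack spanning the leaflet thickness) with
    moderate detector noise; fiber placement follows a von Mises
    orientation distribution with concentration ``kappa`` (0 = isotropic).
    """

    size_px: tuple[int, int] = (500, 500)
    n_slices: int = 14
    pitch_um: float = 0.28
    z_step_um: float = 2.0
    fiber_density: float = 0.10
    kappa: float = 0.0
    mean_angle_deg: float = 0.0
    fiber_width_px: float = 4.0
    fiber_intensity: float = 28000.0
    # per-fiber brightness spread (relative to fiber_intensity): real SHG
    # fiber brightness varies severalfold with fiber thickness/orientation,
    # and the fixed 20,000 cut is calibrated to sit at the edge of a
    # mid-brightness fiber after the min-max stretch
    fiber_intensity_range: tuple[float, float] = (0.35, 1.0)
    fiber_length_frac: tuple[float, float] = (0.3, 0.6)  # of min(size_px)
    droplet_count: int = 6  # leaflet CARS images always show some lipid;
    # the triangle threshold presumes a bright-object tail
    droplet_radius_px: float = 6.0
    droplet_intensity: float = 40000.0
    crystal_count: int = 0
    crystal_length_px: float = 25.0
    crystal_width_px: float = 3.0
    crystal_intensity: float = 60000.0
    background_level: float = 1000.0
    noise_gaussian_sd: float = 300.0
    noise_poisson_scale: float = 0.02
    blur_sigma_px: float = 1.0  # Gaussian PSF proxy; avoids aliased edges
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fiber_density <= 1.0:
            raise ValueError("fiber_density must be in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.droplet_count < 0 or self.crystal_count < 0:
            raise ValueError("counts must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass
class OCTPhantomSpec:
    """Recipe for an OCT volume containing a curved leaflet band.

    Axes are (x, y, z) with z the axial (depth) axis; the axial pitch is
    expressed in *optical-path* µm, i.e. geometric depth multiplied by the
    tissue refractive index, mimicking what the interferometer records.
    Thickness values are geometric µm per leaflet region (region 1 = tip,
    region 3 = base; the tip sits at high x).
    """

    volume_px: tuple[int, int, int] = (135, 12, 100)
    pitch_um: tuple[float, float, float] = (4.0, 4.0, 3.0)
    thickness_um: tuple[float, float, float] = (137.0, 90.0, 80.0)
    curvature_um: float = 30.0
    speckle_contrast: float = 0.8
    background_level: float = 300.0
    tissue_level: float = 3000.0
    refractive_index: float = 1.33
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thickness_um):
            raise ValueError("thickness_um must be positive")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must be in [0, 1]")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        nz = self.volume_px[2]
        depth_um = nz * self.pitch_um[2] / self.refractive_index
        if max(self.thickness_um) + 2 * self.curvature_um > depth_um:
            raise ValueError("band does not fit into the volume depth")


def _sample_orientation(rng: np.random.Generator, mean_deg: float,
                        kappa: float) -> float:
    """Draw a fiber orientation (degrees, period 180) from a von Mises law.

    Orientations are axial data with period pi, so the angle doubling
    trick maps them onto the circular von Mises distribution.
    """
    theta2 = rng.vonmises(math.radians(2.0 * mean_deg), kappa) if kappa > 0 \
        else rng.uniform(-math.pi, math.pi)
    ang = math.degrees(theta2 / 2.0)
    # wrap to [-90, 90)
    return (ang + 90.0) % 180.0 - 90.0


def _rect_footprint(shape, center, angle_deg, length, width):
    """Boolean footprint of a rotated rectangle (a fiber or crystal segment)."""
    a = math.radians(angle_deg)
    # CCW angle with y up; rows grow downward, hence the minus sign
    d = np.array([-math.sin(a), math.cos(a)])     # (drow, dcol) along the segment
    p = np.array([-math.cos(a), -math.sin(a)])    # perpendicular
    c = np.asarray(center, float)
    h, w = length / 2.0, width / 2.0
    corners = np.array([c + h * d + w * p, c + h * d - w * p,
                        c - h * d - w * p, c - h * d + w * p])
    rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _render_fibers(spec: MPMPhantomSpec, rng: np.random.Generator):
    """Per-slice fiber mesh; returns (mask, relative-brightness field, angles)."""
    shape = spec.size_px
    fiber = np.zeros(shape, bool)
    fiber_field = np.zeros(shape, float)   # relative brightness in [0, 1]
    angles: list[float] = []
    if spec.fiber_density > 0:
        target = int(round(spec.fiber_density * fiber.size))
        lo_len = spec.fiber_length_frac[0] * min(shape)
        hi_len = spec.fiber_length_frac[1] * min(shape)
        stalled = 0
        while fiber.sum() < target:
            if stalled > 1000:
                raise RuntimeError(
                    f"fiber_density {spec.fiber_density} unreachable: no "
                    "progress after 1000 consecutive attempts")
            ang = _sample_orientation(rng, spec.mean_angle_deg, spec.kappa)
            center = rng.uniform((0, 0), shape)
            length = rng.uniform(lo_len, hi_len)
            fp = _rect_footprint(shape, center, ang, length, spec.fiber_width_px)
            if not (fp & ~fiber).any():
                stalled += 1
                continue
            stalled = 0
            fiber |= fp
            rel = rng.uniform(*spec.fiber_intensity_range)
            np.maximum(fiber_field, rel * fp, out=fiber_field)
            angles.append(ang)
    return fiber, fiber_field, angles


def _render_stack_objects(spec: MPMPhantomSpec, rng: np.random.Generator):
    """Crystals and droplets are 3-D objects: one layout for the whole stack."""
    shape = spec.size_px
    crystal = np.zeros(shape, bool)
    for _ in range(spec.crystal_count):
        ang = rng.uniform(-90.0, 90.0)
        center = rng.uniform((0, 0), shape)
        crystal |= _rect_footprint(shape, center, ang,
                                   spec.crystal_length_px, spec.crystal_width_px)

    droplet = np.zeros(shape, bool)
    centers: list[np.ndarray] = []
    placed = 0
    attempts = 0
    margin = spec.droplet_radius_px + 1
    # keep droplets apart by more than twice the blur halo so they stay
    # resolvable as distinct objects after the PSF
    min_sep = 2 * (spec.droplet_radius_px + 3 * spec.blur_sigma_px) + 3
    while placed < spec.droplet_count:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place non-overlapping droplets")
        c = rng.uniform((margin, margin),
                        (shape[0] - margin, shape[1] - margin))
        if any(np.hypot(*(c - q)) < min_sep for q in centers):
            continue
        rr, cc = draw_disk(c, spec.droplet_radius_px, shape=shape)
        droplet[rr, cc] = True
        centers.append(c)
        placed += 1
    return crystal, droplet


def _soften(field: np.ndarray, sigma: float) -> np.ndarray:
    img = field.astype(float)
    if sigma > 0:
        img = gaussian_filter(img, sigma, mode="constant")
    return img


def _add_noise_and_quantize(signal: np.ndarray, spec: MPMPhantomSpec,
                            rng: np.random.Generator) -> np.ndarray:
    img = signal + spec.background_level
    if spec.noise_poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0) * spec.noise_poisson_scale) \
            / spec.noise_poisson_scale
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
    return np.rint(np.clip(img, 0, 65535)).astype(np.uint16)


def generate_mpm_phantom(spec: MPMPhantomSpec) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Generate a paired SHG/CARS stack with per-slice truth masks.

    Fibers appear only in SHG, droplets only in CARS, crystals in both.
    Truth fractions are computed from the pre-noise binary footprints:
    collagen is the fiber area not overlapped by crystals (what the
    crystal-corrected measure estimates), crystals their own area.
    """
    rng = np.random.default_rng(spec.seed)
    # crystals and droplets are thicker-than-z-step 3-D objects: one layout
    # shared by every slice, so a maximum-intensity projection sees exactly
    # ``droplet_count`` droplets
    crystal, droplet = _render_stack_objects(spec, rng)
    soft_crystal = _soften(crystal, spec.blur_sigma_px)
    soft_droplet = _soften(droplet, spec.blur_sigma_px)
    cars = np.maximum(spec.droplet_intensity * soft_droplet,
                      spec.crystal_intensity * soft_crystal)
    shg_slices, cars_slices = [], []
    fiber_masks, crystal_masks, droplet_masks = [], [], []
    all_angles: list[float] = []
    collagen_pcts, crystal_pcts = [], []
    for _ in range(spec.n_slices):
        fib, fiber_field, angles = _render_fibers(spec, rng)
        shg = np.maximum(
            spec.fiber_intensity * _soften(fiber_field, spec.blur_sigma_px),
            spec.crystal_intensity * soft_crystal)
        shg_slices.append(_add_noise_and_quantize(shg, spec, rng))
        cars_slices.append(_add_noise_and_quantize(cars, spec, rng))
        fiber_masks.append(fib)
        crystal_masks.append(crystal)
        droplet_masks.append(droplet)
        all_angles.extend(angles)
        collagen_pcts.append(100.0 * np.count_nonzero(fib & ~crystal) / fib.size)
        crystal_pcts.append(100.0 * np.count_nonzero(crystal) / crystal.size)

    truth = PhantomTruth(
        collagen_fraction_pct=float(np.mean(collagen_pcts)),
        crystal_fraction_pct=float(np.mean(crystal_pcts)),
        droplet_count=spec.droplet_count,
        kappa=spec.kappa,
        mean_angle_deg=spec.mean_angle_deg,
        fiber_masks=np.array(fiber_masks),
        crystal_masks=np.array(crystal_masks),
        droplet_masks=np.array(droplet_masks),
        fiber_angles_deg=all_angles,
    )
    shg_stack = ImageStack(np.array(shg_slices), spec.pitch_um,
                           spec.z_step_um, Channel.SHG)
    cars_stack = ImageStack(np.array(cars_slices), spec.pitch_um,
                            spec.z_step_um, Channel.CARS)
    return shg_stack, cars_stack, truth


def generate_oct_phantom(spec: OCTPhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Generate an OCT volume containing a curved leaflet band.

    The band has piecewise-constant geometric thickness per region along
    x (tip at high x) and a parabolic depth offset; its axial extent in
    the volume is the geometric extent times the refractive index, because
    OCT records optical path length. Speckle is multiplicative
    Rayleigh-distributed, blended by ``speckle_contrast``.
    """
    nx, ny, nz = spec.volume_px
    px, py, pz_opt = spec.pitch_um
    n = spec.refractive_index
    rng = np.random.default_rng(spec.seed)

    x_idx = np.arange(nx)
    # region boundaries: equal thirds along x; region 1 = tip = high x
    region_of_x = np.full(nx, 2, int)           # region index 0..2 -> labels 3..1
    region_of_x[x_idx >= nx / 3.0] = 1
    region_of_x[x_idx >= 2.0 * nx / 3.0] = 0
    t_geom = np.array(spec.thickness_um)[region_of_x]  # µm per column

    depth_um = nz * pz_opt                       # optical depth of the volume
    cx = (nx - 1) / 2.0
    z_center_geom = depth_um / n / 2.0 \
        + spec.curvature_um * (((x_idx - cx) / max(cx, 1.0)) ** 2 - 0.5)
    z_top_opt = (z_center_geom - t_geom / 2.0) * n     # optical µm
    z_bot_opt = (z_center_geom + t_geom / 2.0) * n

    z_edges = np.arange(nz + 1) * pz_opt
    # per-voxel coverage of the band along z, per column x
    lo = np.maximum(z_edges[None, :-1], z_top_opt[:, None])
    hi = np.minimum(z_edges[None, 1:], z_bot_opt[:, None])
    coverage = np.clip(hi - lo, 0.0, None) / pz_opt      # (nx, nz)

    base = spec.background_level + (spec.tissue_level - spec.background_level) \
        * coverage[:, None, :]                           # (nx, ny, nz)
    base = np.broadcast_to(base, (nx, ny, nz)).copy()
    if spec.speckle_contrast > 0:
        r = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=base.shape)
        base *= (1.0 - spec.speckle_contrast) + spec.speckle_contrast * r

    vol = OCTVolume(voxels=base.astype(np.float32),
                    pitch_um=(px, py, pz_opt),
                    refractive_index=n, axial_axis=2,
                    axial_is_optical=True, isotropic=False)
    lengths_um = np.bincount(region_of_x, weights=np.full(nx, px), minlength=3)
    area = float(sum(spec.thickness_um[i] * lengths_um[i] for i in range(3)))
    truth = PhantomTruth(
        thickness_um={1: spec.thickness_um[0], 2: spec.thickness_um[1],
                      3: spec.thickness_um[2]},
        area_um2=area,
    )
    return vol, truth


def generate_histo_phantom(size_px: tuple[int, int] = (400, 400),
                           collagen_fraction_pct: float = 50.0,
                           stains: StainMatrix | None = None,
                           seed: int = 0,
                           psr_od: float = 1.0,
                           counter_od: float = 0.25,
                           tolerance_pct: float = 0.5,
                           ) -> tuple[np.ndarray, PhantomTruth]:
    """Generate an RGB picrosirius-red phantom section.

    Collagen-positive blobs carry optical density ``psr_od`` along the red
    stain vector; everything carries a light counterstain. Blobs are added
    until the positive fraction is within ``tolerance_pct`` of the target.
    """
    if not 0.0 <= collagen_fraction_pct <= 100.0:
        raise ValueError("collagen_fraction_pct must be in [0, 100]")
    stains = stains if stains is not None else default_psr_stains()
    rng = np.random.default_rng(seed)
    h, w = size_px
    mask = np.zeros((h, w), bool)
    target = collagen_fraction_pct / 100.0 * mask.size
    attempts = 0
    while mask.sum() < target - tolerance_pct / 100.0 * mask.size:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not reach requested collagen fraction")
        deficit_px = target - mask.sum()
        radius = min(12.0, max(2.0, math.sqrt(deficit_px / math.pi)))
        c = rng.uniform((0, 0), (h, w))
        rr, cc = draw_disk(c, rng.uniform(0.7, 1.0) * radius, shape=(h, w))
        cand = mask.copy()
        cand[rr, cc] = True
        if cand.sum() <= target + tolerance_pct / 100.0 * mask.size:
            mask = cand

    c_psr = psr_od * mask.astype(float)
    c_counter = np.full((h, w), counter_od)
    od = (c_psr[..., None] * stains.psr_red[None, None, :]
          + c_counter[..., None] * stains.counter[None, None, :])
    rgb = od_to_rgb(od)
    truth = PhantomTruth(
        psr_mask=mask,
        psr_fraction_pct=100.0 * np.count_nonzero(mask) / mask.size,
    )
    return rgb, truth
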