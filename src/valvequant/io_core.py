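"""Core data containers and I/O for the valve quantification pipeline.

Physical calibration (pixel pitch, voxel pitch, refractive index) always
travels with the data object: the multiphoton images are sampled at
0.28 µm/px while the OCT volumes end up at 2.255 µm/voxel, and silently
mixing the two is the classic way to get areas wrong by two orders of
magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("valvequant")

__all__ = [
    "Channel",
    "ImageStack",
    "OCTVolume",
    "PipelineConfig",
    "RegionResult",
    "read_stack",
    "write_stack",
    "write_mask",
    "write_results_table",
    "read_results_table",
    "load_config",
    "mask_area_um2",
    "area_fraction_pct",
]


class Channel(str, Enum):
    """Multiphoton acquisition channel."""

    SHG = "SHG"  # second harmonic generation: fibrillar collagen (+ cholesterol crystals)
    CARS = "CARS"  # coherent anti-Stokes Raman at CH2 stretch: lipids + crystals
    TPEF = "TPEF"  # two-photon excited fluorescence: morphology reference


@dataclass
class ImageStack:
    """Ordered z-stack of 2-D 16-bit intensity images with in-plane calibration.

    Parameters
    ----------
    pixels
        Array of shape (n_slices, h, w), dtype uint16.
    pitch_um
        Isotropic in-plane pixel pitch in µm (0.28 µm in the reference
        acquisition).
    z_step_um
        Axial step between slices in µm; varies per stack because stacks
        span the local leaflet thickness with a fixed slice count.
    channel
        Which contrast mechanism the stack records.
    """

    pixels: np.ndarray
    pitch_um: float
    z_step_um: float
    channel: Channel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (n, h, w) array")
        if self.pixels.dtype != np.uint16:
            raise TypeError(
                f"expected 16-bit unsigned data, got {self.pixels.dtype}"
            )
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        self.channel = Channel(self.channel)

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field of view (height, width) in µm."""
        _, h, w = self.pixels.shape
        return (h * self.pitch_um, w * self.pitch_um)


@dataclass
class OCTVolume:
    """3-D OCT intensity volume with per-axis voxel pitch.

    Axes are ordered (x, y, z) where z is the axial (depth) axis by
    default. OCT measures *optical* path length along the axial axis; the
    ``axial_is_optical`` flag records whether the axial pitch is still in
    optical-path units (division by the tissue refractive index converts
    it to geometric length).
    """

    voxels: np.ndarray
    pitch_um: tuple[float, float, float]
    refractive_index: float = 1.33
    axial_axis: int = 2
    axial_is_optical: bool = True
    isotropic: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.pitch_um = tuple(float(p) for p in self.pitch_um)
        if len(self.pitch_um) != 3 or any(p <= 0 for p in self.pitch_um):
            raise ValueError("pitch_um must be three positive values")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if not 0 <= self.axial_axis <= 2:
            raise ValueError("axial_axis must be 0, 1 or 2")


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis chain, with the published defaults.

    The defaults are the constants the reference workflow fixed by manual
    calibration on representative images; every run logs the resolved
    config because each downstream number depends on them.
    """

    shg_threshold: int = 20000
    saturation_pct: float = 0.4
    mean_filter_radius_px: int = 1
    background_radius_px: int = 30
    oct_target_pitch_um: float = 2.255
    refractive_index: float = 1.33
    composite_window: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shg_threshold < 0:
            raise ValueError("shg_threshold must be non-negative")
        if not 0 <= self.saturation_pct < 100:
            raise ValueError("saturation_pct must be in [0, 100)")
        for name in ("mean_filter_radius_px", "background_radius_px",
                     "oct_target_pitch_um", "composite_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def log(self) -> None:
        logger.info("pipeline config: %s", self)


@dataclass
class RegionResult:
    """One quantitative value for one animal / region / metric."""

    animal: str
    region: str
    metric: str
    value: float
    sd: float = float("nan")
    n: int = 1


def read_stack(path: str | Path, pitch_um: float, z_step_um: float,
               channel: Channel | str) -> ImageStack:
    """Read a multi-page 16-bit TIFF as an :class:`ImageStack`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    TypeError
        If the TIFF is not 16-bit unsigned.
    ValueError
        If pages differ in size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page sizes in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.dtype != np.uint16:
        raise TypeError(
            f"{path} is {data.dtype}, expected 16-bit unsigned (uint16)"
        )
    return ImageStack(pixels=data, pitch_um=pitch_um, z_step_um=z_step_um,
                      channel=Channel(channel))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to a multi-page 16-bit TIFF."""
    tifffile.imwrite(Path(path), stack.pixels, photometric="minisblack")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit {0, 255} TIFF for Fiji interoperability."""
    tifffile.imwrite(Path(path),
                     (np.asarray(mask, bool).astype(np.uint8) * 255),
                     photometric="minisblack")


_TABLE_COLUMNS = ["animal", "region", "metric", "value", "sd", "n"]


def write_results_table(results: Sequence[RegionResult], path: str | Path) -> None:
    """Serialize per-region results to CSV, one row per (animal, region, metric).

    NaN standard deviations (n = 1 entries have no spread) are written as
    empty fields and round-trip as NaN; a warning is logged so they are
    not mistaken for data loss.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = [[r.animal, r.region, r.metric, r.value, r.sd, r.n] for r in results]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if df["sd"].isna().any():
        logger.warning("writing %d result rows with undefined SD (n=1)",
                       int(df["sd"].isna().sum()))
    df.to_csv(Path(path), index=False)


def read_results_table(path: str | Path) -> list[RegionResult]:
    """Read back a results CSV written by :func:`write_results_table`."""
    df = pd.read_csv(Path(path), dtype={"animal": str, "region": str})
    return [RegionResult(animal=row.animal, region=row.region,
                         metric=row.metric, value=float(row.value),
                         sd=float(row.sd), n=int(row.n))
            for row in df.itertuples()]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Missing keys take the published defaults; unknown keys are rejected to
    catch typos; invariant violations raise ``ValueError``.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must be a mapping")
            values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**values)
    cfg.log()
    return cfg


def mask_area_um2(mask: np.ndarray, pitch_um: float) -> float:
    """Physical area of a boolean mask: pixel count x pitch^2."""
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    return float(np.count_nonzero(mask)) * pitch_um ** 2


def area_fraction_pct(mask: np.ndarray, denominator: np.ndarray | None = None) -> float:
    """Percentage of pixels that are true, optionally within a denominator mask."""
    mask = np.asarray(mask, bool)
    if denominator is None:
        return 100.0 * np.count_nonzero(mask) / mask.size
    denominator = np.asarray(denominator, bool)
    n = np.count_nonzero(denominator)
    if n == 0:
        raise ValueError("denominator mask is empty")
    return 100.0 * np.count_nonzero(mask & denominator) / n
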