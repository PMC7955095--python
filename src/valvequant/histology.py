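"""Picrosirius-red collagen quantification on RGB histology sections.

Color deconvolution follows the Ruifrok–Johnston optical-density model:
each pixel's RGB transmittance is converted to optical density (OD),
which is the linear mixture of per-stain concentrations along unit OD
vectors; inverting the stain matrix unmixes the stains. The positive
collagen fraction is then the share of leaflet pixels whose red-stain OD
exceeds a manually chosen threshold — the threshold is a required config
value because the reference workflow set it by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import area_fraction_pct

__all__ = [
    "StainMatrix",
    "default_psr_stains",
    "rgb_to_od",
    "od_to_rgb",
    "color_deconvolve",
    "psr_fraction",
    "section_morphometry",
]


@dataclass
class StainMatrix:
    """Unit optical-density vectors (R, G, B) of the three unmixing channels."""

    psr_red: np.ndarray
    counter: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        for name in ("psr_red", "counter", "residual"):
            v = np.asarray(getattr(self, name), float)
            norm = np.linalg.norm(v)
            if norm == 0:
                raise ValueError(f"{name} stain vector is zero")
            setattr(self, name, v / norm)
        if abs(np.linalg.det(self.matrix)) < 1e-6:
            raise ValueError("stain vectors are (nearly) collinear")

    @property
    def matrix(self) -> np.ndarray:
        """Rows are the stain OD vectors."""
        return np.stack([self.psr_red, self.counter, self.residual])


def default_psr_stains() -> StainMatrix:
    """Default stain vectors for picrosirius red with a green counterstain.

    The red-stain vector absorbs strongly in green and blue; the
    counterstain vector is a fast-green-like vector. Both follow the
    published Ruifrok–Johnston style vectors for red/green stain pairs and
    are meant to be overridden per staining batch. The residual channel is
    the unit vector orthogonal to both.
    """
    psr = np.array([0.214, 0.851, 0.478])
    counter = np.array([0.749, 0.606, 0.267])
    residual = np.cross(psr, counter)
    return StainMatrix(psr_red=psr, counter=counter, residual=residual)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density of an 8-bit RGB raster: OD = -log10((I + 1) / 256)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (h, w, 3) RGB raster")
    return -np.log10((rgb.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to 8-bit."""
    rgb = 256.0 * np.power(10.0, -np.asarray(od, float)) - 1.0
    return np.rint(np.clip(rgb, 0, 255)).astype(np.uint8)


def color_deconvolve(rgb: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Unmix an RGB image into per-stain concentration maps.

    Returns an (h, w, 3) array of concentrations in the order
    (psr_red, counter, residual), clipped at zero.
    """
    od = rgb_to_od(rgb)
    conc = od @ np.linalg.inv(stains.matrix)
    return np.clip(conc, 0.0, None)


def psr_fraction(psr_od: np.ndarray, leaflet_mask: np.ndarray | None,
                 threshold_od: float) -> float:
    """Percent of leaflet pixels whose red-stain OD exceeds the threshold."""
    psr_od = np.asarray(psr_od, float)
    positive = psr_od > threshold_od
    if leaflet_mask is None:
        return 100.0 * np.count_nonzero(positive) / positive.size
    leaflet_mask = np.asarray(leaflet_mask, bool)
    if not leaflet_mask.any():
        raise ValueError("leaflet mask is empty")
    return area_fraction_pct(positive, leaflet_mask)


def section_morphometry(mask: np.ndarray, grid, pitch_um: float):
    """Area and region thickness of a histology section mask.

    Shares the measurement operators with the OCT path so that OCT and
    histology numbers are directly comparable (e.g. for shrinkage ratios).
    """
    from .oct import measure_area, measure_thickness, MorphometryResult

    area = measure_area(mask, pitch_um)
    thickness = measure_thickness(mask, grid, pitch_um)
    return MorphometryResult(area_um2=area, thickness_um=thickness,
                             source="HISTOLOGY")
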