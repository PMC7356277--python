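"""Vegetation indices and canopy-cover extraction from multispectral imagery.

Plot rasters are ``(rows, cols, 3)`` float arrays with band order
``(green, red, nir)`` and reflectance in [0, 1].  Canopy cover is the
fraction of pixels classified as vegetation by thresholding the
soil-adjusted vegetation index (SAVI); plot NDVI is the per-pixel mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "CanopyPoint",
    "compute_ndvi",
    "compute_savi",
    "segment_canopy_cover",
    "plot_mean_index",
    "cover_from_mixture",
]

#: Standard soil-adjustment factor for SAVI.
DEFAULT_SAVI_L = 0.5

#: Default SAVI segmentation threshold (the alternative is ``"otsu"``).
DEFAULT_SAVI_THRESHOLD = 0.3

BAND_GREEN, BAND_RED, BAND_NIR = 0, 1, 2


@dataclass(frozen=True)
class CanopyPoint:
    """Canopy state of one plot at one flight: cover fraction and mean NDVI."""

    dap: int
    cc: float
    ndvi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cc <= 1.0:
            raise ValueError(f"canopy cover {self.cc} outside [0, 1]")
        if not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(f"NDVI {self.ndvi} outside [-1, 1]")


def compute_ndvi(nir, red):
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    if np.any(denom == 0):
        raise ValueError("NDVI undefined where nir + red = 0")
    out = (nir - red) / denom
    return float(out) if out.ndim == 0 else out


def compute_savi(nir, red, L: float = DEFAULT_SAVI_L):
    """Soil-adjusted vegetation index (NIR - Red)(1 + L)/(NIR + Red + L)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be non-negative")
    if L <= 0:
        raise ValueError("soil factor L must be > 0")
    out = (nir - red) * (1.0 + L) / (nir + red + L)
    return float(out) if out.ndim == 0 else out


def _check_raster(raster: np.ndarray) -> np.ndarray:
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise ValueError("empty raster")
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError("raster must have shape (rows, cols, 3) = (green, red, nir)")
    return raster


def segment_canopy_cover(raster: np.ndarray, threshold=DEFAULT_SAVI_THRESHOLD,
                         L: float = DEFAULT_SAVI_L) -> float:
    """Fraction of pixels whose SAVI strictly exceeds the threshold.

    ``threshold`` is a fixed SAVI value or ``"otsu"`` for an automatic
    bimodal split.  Pixels exactly at the threshold count as soil.
    """
    raster = _check_raster(raster)
    savi = compute_savi(raster[..., BAND_NIR], raster[..., BAND_RED], L=L)
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        threshold = float(threshold_otsu(np.asarray(savi)))
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return float(np.mean(savi > threshold))


def plot_mean_index(raster: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean per-pixel NDVI over a plot raster (optionally within a mask)."""
    raster = _check_raster(raster)
    ndvi = compute_ndvi(raster[..., BAND_NIR], raster[..., BAND_RED])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ndvi.shape:
            raise ValueError("mask shape does not match raster")
        if not mask.any():
            raise ValueError("empty mask region")
        ndvi = ndvi[mask]
    return float(np.mean(ndvi))


def cover_from_mixture(nir, veg_nir: float, soil_nir: float):
    """Invert a linear two-endmember mixture on the NIR band to canopy cover.

    For plot-mean reflectance tables (no raster available) the NIR band is a
    linear blend ``cc * veg + (1 - cc) * soil``; this solves for cc, clipped
    to [0, 1].
    """
    if veg_nir == soil_nir:
        raise ValueError("degenerate endmembers: veg and soil NIR are equal")
    cc = (np.asarray(nir, dtype=float) - soil_nir) / (veg_nir - soil_nir)
    cc = np.clip(cc, 0.0, 1.0)
    return float(cc) if cc.ndim == 0 else cc
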