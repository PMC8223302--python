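"""Hyperspectral i-traits: per-band reflectance statistics and derivatives.

A scan is a 250-band reflectance cube (~400-1000 nm).  Over the segmented
plant pixels two base profiles are computed per band b: total reflectance
T_b (sum) and average reflectance A_b (mean).  Eight trait families --
T, A, lgT, lgA (base-10 logs) and the first/second spectral derivatives
dT, dA, ddT, ddA -- give 8 x 250 = 2000 i-traits per scan.  Band index and
wavelength are linked by a linear calibration anchored at band 15 = 434 nm
and band 233 = 959 nm (so e.g. dT233 is the first derivative of total
reflectance at 959 nm and lgA15 the log of the 434 nm average reflectance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HSICube", "SpectralProfile", "band_wavelength", "nearest_band",
           "extract_spectral_profile", "extract_hsi_traits", "segment_cube",
           "HSI_FAMILIES", "N_BANDS"]

N_BANDS = 250
HSI_FAMILIES = ("T", "A", "lgT", "lgA", "dT", "dA", "ddT", "ddA")

_ANCHOR_BAND = (15, 233)
_ANCHOR_NM = (434.0, 959.0)
_NM_PER_BAND = (_ANCHOR_NM[1] - _ANCHOR_NM[0]) / (_ANCHOR_BAND[1] - _ANCHOR_BAND[0])


@dataclass
class HSICube:
    """bands x height x width reflectance array plus scan metadata."""

    data: np.ndarray
    accession: str = ""
    treatment: str = ""
    day: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube must be bands x height x width")
        if np.nanmin(self.data) < 0:
            raise ValueError("reflectance values must be >= 0")


@dataclass
class SpectralProfile:
    """Per-band totals and averages over the plant pixels."""

    total: np.ndarray
    average: np.ndarray
    plant_pixel_count: int


def band_wavelength(band: int, n_bands: int = N_BANDS) -> float:
    """Wavelength (nm) of a 1-based band index.

    Linear map through the anchors (band 15, 434 nm) and (band 233, 959 nm):
    lambda(b) = 434 + (b - 15) * (959 - 434) / (233 - 15).
    """
    if not 1 <= band <= n_bands:
        raise ValueError(f"band {band} out of range 1..{n_bands}")
    return _ANCHOR_NM[0] + (band - _ANCHOR_BAND[0]) * _NM_PER_BAND


def nearest_band(wavelength_nm: float, n_bands: int = N_BANDS) -> int:
    """Inverse lookup: the band whose wavelength is closest to the query."""
    b = round((wavelength_nm - _ANCHOR_NM[0]) / _NM_PER_BAND + _ANCHOR_BAND[0])
    b = int(min(max(b, 1), n_bands))
    return b


def band_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    return np.array([band_wavelength(b, n_bands) for b in range(1, n_bands + 1)])


def segment_cube(cube: HSICube, red_nm: float = 670.0,
                 nir_nm: float = 800.0) -> np.ndarray:
    """Segment plant pixels with an NDVI-like red/NIR band contrast.

    Vegetation is bright in the NIR and dark in the red, so
    (NIR - red)/(NIR + red) separates leaf from background; the threshold
    is Otsu's on the contrast image.  Degenerate contrast yields an empty
    mask with a warning.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    n_bands = cube.data.shape[0]
    red = cube.data[nearest_band(red_nm, n_bands) - 1].astype(float)
    nir = cube.data[nearest_band(nir_nm, n_bands) - 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red > 0, (nir - red) / (nir + red), 0.0)
    if np.ptp(ndvi) < 1e-6:
        warnings.warn("degenerate contrast: no red/NIR separation, empty mask")
        return np.zeros(ndvi.shape, dtype=bool)
    mask = ndvi > threshold_otsu(ndvi)
    lab = label(mask)
    if lab.max() == 0:
        warnings.warn("no plant pixels above NDVI threshold")
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def extract_spectral_profile(cube: HSICube, mask: np.ndarray | None = None
                             ) -> SpectralProfile:
    """Total and average reflectance per band over plant pixels.

    ``mask`` defaults to the NDVI-like segmentation of the cube itself.
    """
    if mask is None:
        mask = segment_cube(cube)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[1:]:
        raise ValueError("mask and cube spatial dimensions differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no plant pixels")
    pix = cube.data[:, mask].astype(float)
    total = pix.sum(axis=1)
    return SpectralProfile(total=total, average=total / n, plant_pixel_count=n)


def _second_difference(x: np.ndarray) -> np.ndarray:
    """Second central difference, one-sided at both ends (unit band step)."""
    dd = np.empty_like(x, dtype=float)
    dd[1:-1] = x[2:] - 2 * x[1:-1] + x[:-2]
    dd[0] = x[2] - 2 * x[1] + x[0]
    dd[-1] = x[-1] - 2 * x[-2] + x[-3]
    return dd


def extract_hsi_traits(profile: SpectralProfile) -> pd.Series:
    """The 2000-trait registry of one scan, named like T55, lgA15, ddT200.

    Derivatives are taken with respect to band index with unit step
    (central differences inside, one-sided at the ends); logs are base 10
    with non-positive arguments missing-coded as NaN.
    """
    T = np.asarray(profile.total, dtype=float)
    A = np.asarray(profile.average, dtype=float)
    n = T.size
    with np.errstate(divide="ignore", invalid="ignore"):
        lgT = np.where(T > 0, np.log10(np.where(T > 0, T, 1.0)), np.nan)
        lgA = np.where(A > 0, np.log10(np.where(A > 0, A, 1.0)), np.nan)
    values = {
        "T": T, "A": A, "lgT": lgT, "lgA": lgA,
        "dT": np.gradient(T), "dA": np.gradient(A),
        "ddT": _second_difference(T), "ddA": _second_difference(A),
    }
    out = {}
    for fam in HSI_FAMILIES:
        for b in range(1, n + 1):
            out[f"{fam}{b}"] = values[fam][b - 1]
    return pd.Series(out)
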