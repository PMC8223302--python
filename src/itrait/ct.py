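"""CT i-traits: filtered back-projection and culm morphometrics.

A scan is a sinogram of 360 X-ray projections at 1-degree steps.  The slice
is reconstructed by filtered back-projection (ramp filter by default) and
the culm cross-section is segmented at an intensity-threshold ladder
tau in {100, 200, ..., 1000}; ten measures per threshold (culm diameter,
hollow/material/total areas, wall thickness, outer perimeter, hollow
fraction, eccentricity, mean material intensity, hollow-centroid offset)
give the 100-trait CT registry.  The enclosed sub-threshold region inside
the material ring is the "hollow" -- the culm cavity whose size shrinks
under drought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, perimeter, regionprops
from skimage.transform import iradon

__all__ = ["Sinogram", "CTSlice", "reconstruct_slice",
           "segment_culm_at_threshold", "extract_ct_traits",
           "CT_THRESHOLDS", "CT_MEASURES", "CT_TRAIT_NAMES"]

CT_THRESHOLDS = tuple(range(100, 1001, 100))
CT_MEASURES = (
    "culm_diameter", "hollow_area", "material_area", "total_area",
    "wall_thickness", "outer_perimeter", "hollow_fraction", "eccentricity",
    "mean_material_intensity", "hollow_centroid_offset",
)
CT_TRAIT_NAMES = [f"{m}_{t}" for m in CT_MEASURES for t in CT_THRESHOLDS]


@dataclass
class Sinogram:
    """projections x detector-bins array with a uniform angular step."""

    data: np.ndarray
    angle_step_deg: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("sinogram needs >= 2 projections")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.angle_step_deg


@dataclass
class CTSlice:
    data: np.ndarray
    um_per_px: float = 36.0


def reconstruct_slice(sinogram: Sinogram, filter_name: str = "ramp") -> CTSlice:
    """Filtered back-projection inverse of the discrete Radon transform.

    Output is square with side equal to the detector-bin count.  Angular
    coverage below 180 degrees triggers a limited-angle warning (the
    reconstruction proceeds but streak artifacts are expected).
    """
    coverage = sinogram.angle_step_deg * sinogram.data.shape[0]
    if coverage < 180.0:
        warnings.warn(f"angular coverage {coverage:.0f} deg < 180 deg: "
                      "limited-angle artifacts expected")
    n_det = sinogram.data.shape[1]
    img = iradon(sinogram.data.T, theta=sinogram.angles,
                 filter_name=filter_name, interpolation="linear",
                 output_size=n_det, circle=True)
    return CTSlice(img)


def segment_culm_at_threshold(ct_slice: CTSlice, tau: float):
    """Material and hollow masks at intensity threshold ``tau``.

    Material = largest connected component of pixels >= tau; hollow = the
    enclosed sub-threshold region inside that ring (holes of the material
    mask).  No pixel above threshold yields two empty masks with a warning.
    """
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    img = np.asarray(ct_slice.data)
    above = img >= tau
    if not above.any():
        warnings.warn(f"no pixel >= threshold {tau}; empty masks")
        empty = np.zeros(img.shape, bool)
        return empty, empty.copy()
    lab = label(above)
    sizes = np.bincount(lab.ravel())[1:]
    material = lab == (int(np.argmax(sizes)) + 1)
    hollow = binary_fill_holes(material) & ~material
    return material, hollow


def _wall_thickness(material: np.ndarray, n_rays: int = 360) -> float:
    """Mean (outer radius - inner radius) over rays cast from the centroid."""
    ys, xs = np.nonzero(material)
    cy, cx = ys.mean(), xs.mean()
    r_max = np.hypot(ys - cy, xs - cx).max()
    radii = np.arange(0.0, r_max + 1.0, 0.25)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    yy = np.rint(cy + radii[None, :] * np.sin(angles)[:, None]).astype(int)
    xx = np.rint(cx + radii[None, :] * np.cos(angles)[:, None]).astype(int)
    inside = ((yy >= 0) & (yy < material.shape[0])
              & (xx >= 0) & (xx < material.shape[1]))
    hit = np.zeros_like(inside)
    hit[inside] = material[yy[inside], xx[inside]]
    thick = []
    for k in range(n_rays):
        r_hit = radii[hit[k]]
        if r_hit.size:
            thick.append(r_hit.max() - r_hit.min())
    return float(np.mean(thick)) if thick else np.nan


def extract_ct_traits(ct_slice: CTSlice,
                      thresholds=CT_THRESHOLDS) -> pd.Series:
    """The 100-trait CT registry: 10 measures at each of 10 thresholds.

    Measures at thresholds with an empty segmentation are missing-coded.
    The culm diameter is the maximal Feret diameter of the material+hollow
    union; lengths/areas are in px and px^2 (multiply by the slice
    um_per_px calibration for physical units).
    """
    out = {}
    img = np.asarray(ct_slice.data)
    for tau in thresholds:
        keys = {m: f"{m}_{tau}" for m in CT_MEASURES}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            material, hollow = segment_culm_at_threshold(ct_slice, tau)
        if not material.any():
            for k in keys.values():
                out[k] = np.nan
            continue
        union = material | hollow
        props = regionprops(union.astype(np.uint8))[0]
        mat_area = int(material.sum())
        hol_area = int(hollow.sum())
        tot_area = int(union.sum())
        out[keys["culm_diameter"]] = float(props.feret_diameter_max)
        out[keys["hollow_area"]] = float(hol_area)
        out[keys["material_area"]] = float(mat_area)
        out[keys["total_area"]] = float(tot_area)
        out[keys["wall_thickness"]] = _wall_thickness(material)
        out[keys["outer_perimeter"]] = float(perimeter(union, neighborhood=8))
        out[keys["hollow_fraction"]] = hol_area / tot_area
        out[keys["eccentricity"]] = float(props.eccentricity)
        out[keys["mean_material_intensity"]] = float(img[material].mean())
        if hol_area:
            hy, hx = np.nonzero(hollow)
            uy, ux = props.centroid
            out[keys["hollow_centroid_offset"]] = float(
                np.hypot(hy.mean() - uy, hx.mean() - ux))
        else:
            out[keys["hollow_centroid_offset"]] = 0.0
    return pd.Series(out)[CT_TRAIT_NAMES]
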