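"""RGB i-traits: silhouette segmentation and the 67-trait registry.

Each scan is a stack of side views (20 by default, one per 18 degrees of
turntable rotation).  The view with the widest segmented silhouette is
selected and traits are computed on it: 15 geometry/architecture traits
(led by TPA, the total projected area), 12 color summaries over plant
pixels, and 40 hue-histogram bin fractions -- 67 per scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label, perimeter, regionprops
from skimage.morphology import footprint_rectangle, opening, skeletonize

__all__ = ["RGBScan", "PlantMask", "segment_plant", "select_max_width_view",
           "extract_rgb_traits", "RGB_TRAIT_NAMES", "N_RGB_TRAITS"]

N_HUE_BINS = 40

_GEOMETRY = [
    "TPA", "plant_height", "plant_width", "height_width_ratio",
    "convex_hull_area", "solidity", "perimeter", "bbox_fill_ratio",
    "centroid_height_fraction", "top_half_area_fraction", "compactness",
    "max_extent_left", "max_extent_right", "skeleton_length", "stem_width",
]
_COLOR = [f"{s}_{c}" for c in ("r", "g", "b", "hue", "sat", "val")
          for s in ("mean", "std")]
RGB_TRAIT_NAMES = (_GEOMETRY + _COLOR
                   + [f"hue_bin_{i:02d}" for i in range(N_HUE_BINS)])
N_RGB_TRAITS = len(RGB_TRAIT_NAMES)  # 15 + 12 + 40 = 67


@dataclass
class RGBScan:
    """Ordered side views of one plant plus scan metadata."""

    views: list
    accession: str = ""
    treatment: str = ""
    day: int = 0
    soil_moisture: float = float("nan")
    mm_per_px: float | None = None

    def __post_init__(self):
        if len(self.views) < 1:
            raise ValueError("a scan needs at least one view")
        shapes = {np.asarray(v).shape for v in self.views}
        if len(shapes) != 1:
            raise ValueError("all views must share dimensions")


@dataclass
class PlantMask:
    mask: np.ndarray
    view_index: int = 0
    area_px: int = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())


def segment_plant(view: np.ndarray, open_size: int = 3,
                  view_index: int = 0) -> PlantMask:
    """Segment plant pixels by excess-green thresholding.

    The excess-green index ExG = 2G - R - B is near zero for gray/white
    background and large for foliage; the cut is Otsu's threshold on ExG,
    followed by a morphological opening and largest-connected-component
    selection.  Degenerate contrast produces an empty mask with a warning,
    never a crash.
    """
    img = np.asarray(view, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    exg = 2.0 * img[..., 1] - img[..., 0] - img[..., 2]
    if np.ptp(exg) < 1e-9:
        warnings.warn("degenerate contrast: foreground indistinguishable by "
                      "the greenness criterion; returning empty mask")
        return PlantMask(np.zeros(exg.shape, bool), view_index)
    thr = threshold_otsu(exg)
    mask = exg > max(thr, 0.0)
    if open_size > 1:
        mask = opening(mask, footprint_rectangle((open_size, open_size)))
    lab = label(mask)
    if lab.max() == 0:
        warnings.warn("no plant detected in view; returning empty mask")
        return PlantMask(mask, view_index)
    sizes = np.bincount(lab.ravel())[1:]
    return PlantMask(lab == (int(np.argmax(sizes)) + 1), view_index)


def _mask_width(mask: np.ndarray) -> int:
    cols = np.flatnonzero(mask.any(axis=0))
    return int(cols[-1] - cols[0] + 1) if cols.size else 0


def select_max_width_view(scan: RGBScan, masks: list[PlantMask] | None = None
                          ) -> int:
    """Index of the view with maximal horizontal plant extent (ties -> lowest)."""
    if masks is None:
        masks = [segment_plant(v, view_index=i) for i, v in enumerate(scan.views)]
    widths = [_mask_width(m.mask) for m in masks]
    if max(widths, default=0) == 0:
        raise ValueError("no plant detected in any view")
    return int(np.argmax(widths))


def extract_rgb_traits(scan: RGBScan) -> pd.Series:
    """The 67-trait registry for one scan, computed on the max-width view.

    An empty plant yields zero geometric traits and missing-coded (NaN)
    color traits.  TPA is in px^2 unless the scan carries an mm-per-pixel
    calibration, in which case areas are mm^2 and lengths mm.
    """
    masks = [segment_plant(v, view_index=i) for i, v in enumerate(scan.views)]
    widths = [_mask_width(m.mask) for m in masks]
    idx = int(np.argmax(widths)) if max(widths, default=0) > 0 else 0
    mask = masks[idx].mask
    view = np.asarray(scan.views[idx], dtype=float)

    s = scan.mm_per_px if scan.mm_per_px else 1.0
    out = dict.fromkeys(RGB_TRAIT_NAMES, 0.0)
    area = int(mask.sum())

    if area == 0:
        for name in RGB_TRAIT_NAMES[15:]:
            out[name] = np.nan
        return pd.Series(out)[RGB_TRAIT_NAMES]

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    height = int(rows[-1] - rows[0] + 1)
    width = int(cols[-1] - cols[0] + 1)
    props = regionprops(mask.astype(np.uint8))[0]
    perim = perimeter(mask, neighborhood=8)
    cy, cx = props.centroid

    out["TPA"] = area * s ** 2
    out["plant_height"] = height * s
    out["plant_width"] = width * s
    out["height_width_ratio"] = height / width
    out["convex_hull_area"] = props.area_convex * s ** 2
    out["solidity"] = props.solidity
    out["perimeter"] = perim * s
    out["bbox_fill_ratio"] = area / (height * width)
    out["centroid_height_fraction"] = (rows[-1] - cy) / max(height - 1, 1)
    mid = int(rows[0] + height // 2)
    out["top_half_area_fraction"] = float(mask[rows[0]:mid].sum()) / area
    out["compactness"] = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
    out["max_extent_left"] = (cx - cols[0]) * s
    out["max_extent_right"] = (cols[-1] - cx) * s
    out["skeleton_length"] = int(skeletonize(mask).sum()) * s
    # stem width: median row width over the bottom 10% of plant rows
    bottom = rows[rows >= rows[-1] - max(height // 10, 1) + 1]
    out["stem_width"] = float(np.median(mask[bottom].sum(axis=1))) * s

    rgb = view[mask] / (255.0 if view.max() > 1.0 else 1.0)
    hsv = rgb2hsv(rgb.reshape(-1, 1, 3)).reshape(-1, 3)
    channels = {"r": rgb[:, 0], "g": rgb[:, 1], "b": rgb[:, 2],
                "hue": hsv[:, 0], "sat": hsv[:, 1], "val": hsv[:, 2]}
    for name, vals in channels.items():
        out[f"mean_{name}"] = float(vals.mean())
        out[f"std_{name}"] = float(vals.std())
    hist, _ = np.histogram(hsv[:, 0], bins=N_HUE_BINS, range=(0.0, 1.0))
    for i in range(N_HUE_BINS):
        out[f"hue_bin_{i:02d}"] = hist[i] / area
    return pd.Series(out)[RGB_TRAIT_NAMES]
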