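"""Image phantoms with analytic ground truth for the three scanner modalities.

Stands in for greenhouse scans: a rasterized plant silhouette with an exact
foreground pixel count (RGB stack), the same silhouette carrying a
parametric leaf reflectance spectrum over 250 bands (HSI cube), and a
hollow-culm annulus slice forward-projected into a 360-view sinogram (CT).
Geometry and spectra are deterministic functions of the spec, so every
downstream trait has a known expected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse
from skimage.transform import radon

from .hsi import band_wavelength

__all__ = ["PhantomSpec", "PhantomScanSet", "make_image_phantoms",
           "leaf_spectrum", "plant_silhouette", "annulus_slice"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic plant/culm phantom.

    Radii are in pixels; intensities are on the reconstructed-intensity
    scale; reflectance vectors have one value in [0, 1] per band.
    """

    plant_area_px: int = 12_000
    plant_height_px: int = 200
    plant_width_px: int = 150
    leaf_reflectance: np.ndarray = None
    background_reflectance: np.ndarray = None
    culm_outer_radius_px: float = 40.0
    culm_inner_radius_px: float = 25.0
    material_intensity: float = 1000.0
    background_intensity: float = 0.0
    n_views: int = 20
    n_bands: int = 250
    n_projections: int = 360
    ct_grid: int = 128
    hsi_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if not self.culm_inner_radius_px < self.culm_outer_radius_px:
            raise ValueError("culm inner radius must be < outer radius")
        if self.leaf_reflectance is None:
            self.leaf_reflectance = leaf_spectrum(self.n_bands)
        if self.background_reflectance is None:
            self.background_reflectance = np.full(self.n_bands, 0.05)
        self.leaf_reflectance = np.asarray(self.leaf_reflectance, float)
        self.background_reflectance = np.asarray(self.background_reflectance, float)
        for v in (self.leaf_reflectance, self.background_reflectance):
            if v.shape != (self.n_bands,):
                raise ValueError("reflectance vectors must have length n_bands")
            if v.min() < 0 or v.max() > 1:
                raise ValueError("reflectance values must lie in [0, 1]")


@dataclass
class PhantomScanSet:
    """The three synthetic scans plus their ground truth."""

    rgb_stack: np.ndarray        # (n_views, H, W, 3) uint8
    hsi_cube: np.ndarray         # (n_bands, H, W) float32
    sinogram: np.ndarray         # (n_projections, detector_bins)
    ct_slice_truth: np.ndarray   # (grid, grid) ground-truth slice
    mask: np.ndarray             # silhouette used in RGB/HSI views
    spec: PhantomSpec
    ground_truth: dict = field(default_factory=dict)


def leaf_spectrum(n_bands: int = 250, chlorophyll: float = 1.0,
                  water: float = 1.0) -> np.ndarray:
    """Smooth vegetation-like reflectance over the 400-1000 nm band grid.

    Features: green peak near 550 nm, chlorophyll absorption (red valley)
    near 670 nm deepening with ``chlorophyll``, a red edge over 680-760 nm
    rising to the NIR plateau, and a water-absorption dip at 960 nm whose
    depth scales with ``water``.
    """
    lam = np.array([band_wavelength(b, n_bands=n_bands) for b in range(1, n_bands + 1)])

    def g(mu, s):
        return np.exp(-0.5 * ((lam - mu) / s) ** 2)

    base = (0.10
            - 0.060 * chlorophyll * g(670.0, 28.0)
            - 0.050 * chlorophyll * g(470.0, 35.0)
            + 0.080 * g(550.0, 32.0)
            + 0.50 / (1.0 + np.exp(-(lam - 712.0) / 14.0)))
    dip = 1.0 - 0.35 * water * g(960.0, 35.0)
    return np.clip(base * dip, 0.01, 0.95)


def plant_silhouette(area_px: int, height_px: int, width_px: int,
                     n_leaves: int = 6, margin: int = 6) -> np.ndarray:
    """Rasterize a stem + leaf-blob silhouette with exactly ``area_px``
    foreground pixels.

    The stem is a rectangle of the full plant height; leaves are ellipses
    alternating left/right.  Leaf thickness is binary-searched so the pixel
    count lands just below the target, then the stem is locally widened by
    the residual pixel deficit, giving an exact, connected, deterministic
    mask.
    """
    H, W = height_px + 2 * margin, width_px + 2 * margin
    cx = W // 2
    stem_w = max(5, round(0.06 * width_px))
    top, bottom = margin, margin + height_px - 1

    def build(thickness: float) -> np.ndarray:
        m = np.zeros((H, W), dtype=bool)
        m[top:bottom + 1, cx - stem_w // 2: cx - stem_w // 2 + stem_w] = True
        for k in range(n_leaves):
            frac = 0.15 + 0.7 * k / max(n_leaves - 1, 1)
            cy = bottom - frac * height_px
            side = 1 if k % 2 == 0 else -1
            reach = (width_px / 2 - 2) * (1.0 - 0.55 * frac)
            ecx = cx + side * (stem_w / 2 + reach / 2)
            rr, cc = ellipse(cy, ecx, max(thickness, 1.0), max(reach / 2 + 2, 2),
                             shape=m.shape)
            m[rr, cc] = True
        return m

    min_area = build(1.0).sum()
    if area_px < min_area:
        raise ValueError(
            f"plant_area_px={area_px} below minimal silhouette area {min_area}")
    lo, hi = 1.0, float(height_px)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if build(mid).sum() <= area_px:
            lo = mid
        else:
            hi = mid
    mask = build(lo)
    deficit = int(area_px - mask.sum())
    # widen the stem column by column (3 px blocks survive a 3x3 opening)
    col = cx + stem_w - stem_w // 2
    rows = np.arange(top, bottom + 1)
    while deficit > 0 and col < W:
        free = rows[~mask[rows, col]]
        take = free[:deficit]
        mask[take, col] = True
        deficit -= take.size
        col += 1
    if deficit > 0:
        raise ValueError("could not reach requested area inside the canvas")
    return mask


def annulus_slice(grid: int, outer: float, inner: float,
                  material: float, background: float) -> np.ndarray:
    """Ground-truth culm cross-section: a material ring with a hollow core."""
    if 2 * outer >= grid:
        raise ValueError("culm radii exceed the slice extent")
    img = np.full((grid, grid), background, dtype=float)
    c = (grid - 1) / 2.0
    rr, cc = disk((c, c), outer, shape=img.shape)
    img[rr, cc] = material
    rr, cc = disk((c, c), inner, shape=img.shape)
    img[rr, cc] = background
    return img


def make_image_phantoms(spec: PhantomSpec) -> PhantomScanSet:
    """Generate the RGB stack, HSI cube and CT sinogram for one phantom.

    All RGB views share the silhouette, so each view's foreground count
    equals ``plant_area_px`` exactly.  The sinogram is the discrete Radon
    transform of the annulus ground-truth slice at 1-degree steps (for the
    default 360 projections).
    """
    rng = np.random.default_rng(spec.seed)
    mask = plant_silhouette(spec.plant_area_px, spec.plant_height_px,
                            spec.plant_width_px)
    H, W = mask.shape

    view = np.full((H, W, 3), 255, dtype=np.uint8)
    view[mask] = (46, 160, 48)
    rgb_stack = np.repeat(view[None], spec.n_views, axis=0)

    cube = np.empty((spec.n_bands, H, W), dtype=np.float32)
    cube[:] = spec.background_reflectance[:, None, None]
    fg = spec.leaf_reflectance[:, None] * np.ones((1, int(mask.sum())))
    if spec.hsi_noise_sd > 0:
        fg = fg + rng.normal(scale=spec.hsi_noise_sd, size=fg.shape)
    cube[:, mask] = np.clip(fg, 0.0, 1.0)

    ct_truth = annulus_slice(spec.ct_grid, spec.culm_outer_radius_px,
                             spec.culm_inner_radius_px,
                             spec.material_intensity, spec.background_intensity)
    step = 360.0 / spec.n_projections
    theta = np.arange(spec.n_projections) * step
    sinogram = radon(ct_truth, theta=theta).T  # (projections, detector bins)

    c = (spec.ct_grid - 1) / 2.0
    yy, xx = np.mgrid[:spec.ct_grid, :spec.ct_grid]
    rad = np.hypot(yy - c, xx - c)
    gt = {
        "plant_area_px": int(mask.sum()),
        "plant_height_px": int(mask.any(axis=1).sum()),
        "plant_width_px": int(np.ptp(np.flatnonzero(mask.any(axis=0))) + 1),
        "hollow_area_px": int(((rad < spec.culm_inner_radius_px)).sum()),
        "material_area_px": int(((rad < spec.culm_outer_radius_px)
                                 & (rad >= spec.culm_inner_radius_px)).sum()),
        "outer_radius_px": spec.culm_outer_radius_px,
        "inner_radius_px": spec.culm_inner_radius_px,
        "angle_step_deg": step,
    }
    return PhantomScanSet(rgb_stack, cube, sinogram, ct_truth, mask, spec, gt)
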