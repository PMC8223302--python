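"""End-to-end helpers: run one plant through the full experimental design.

The seedling/flowering design mirrors the greenhouse trial: RGB scans at 10
time points (D25-D52, every 3 days), HSI at 4 (D34-D52, every 6 days), CT
at 3 flowering-stage time points (D84-D98, every 7 days), each under WW and
DS.  The drought arm grows more slowly, loses leaf water (deeper 960-nm
absorption) and thins its culm, so DS/WW ratio traits carry signal in the
documented directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import radon

from .ct import CTSlice, Sinogram, extract_ct_traits, reconstruct_slice
from .hsi import HSICube, extract_hsi_traits, extract_spectral_profile
from .phantoms import annulus_slice, leaf_spectrum, plant_silhouette
from .rgb import RGBScan, extract_rgb_traits

RGB_DAYS = tuple(range(25, 53, 3))      # 10 seedling time points
HSI_DAYS = (34, 40, 46, 52)             # 4 seedling time points
CT_DAYS = (84, 91, 98)                  # 3 flowering time points

__all__ = ["RGB_DAYS", "HSI_DAYS", "CT_DAYS", "full_design_records"]


def _growth(day: int, treatment: str) -> float:
    """Relative plant size over the drought course (DS lags after D25)."""
    rel = (day - 20) / 80.0
    if treatment == "DS":
        rel *= max(0.45, 1.0 - 0.02 * (day - 25))
    return rel


def full_design_records(seed: int = 0, accession: str = "acc0000",
                        replicate: int = 1, n_views: int = 20) -> pd.DataFrame:
    """Extract the full 26,910-column design for one synthetic plant.

    Returns long records (accession, replicate, treatment, day, modality,
    trait, value) ready for ``assemble_trait_table``: 67 RGB traits x 10
    days, 2000 HSI x 4, 100 CT x 3, each under both watering arms.
    """
    rng = np.random.default_rng(seed)
    records = []

    def add(traits: pd.Series, treatment: str, day: int, modality: str):
        records.append(pd.DataFrame({
            "accession": accession, "replicate": replicate,
            "treatment": treatment, "day": day, "modality": modality,
            "trait": traits.index, "value": traits.to_numpy(),
        }))

    for treatment in ("WW", "DS"):
        water = 1.0 if treatment == "WW" else 0.55
        for day in RGB_DAYS:
            rel = _growth(day, treatment)
            area = int(6000 + 14000 * rel) + int(rng.integers(0, 200))
            mask = plant_silhouette(area, int(120 + 160 * rel),
                                    int(100 + 90 * rel))
            view = np.full(mask.shape + (3,), 255, dtype=np.uint8)
            view[mask] = (46, 160, 48)
            scan = RGBScan([view] * n_views, accession=accession,
                           treatment=treatment, day=day)
            add(extract_rgb_traits(scan), treatment, day, "RGB")
        for day in HSI_DAYS:
            rel = _growth(day, treatment)
            mask = plant_silhouette(int(6000 + 14000 * rel),
                                    int(120 + 160 * rel),
                                    int(100 + 90 * rel))
            spectrum = leaf_spectrum(water=water * (1 - 0.002 * (day - 34)))
            cube = np.full((250,) + mask.shape, 0.05, dtype=np.float32)
            cube[:, mask] = spectrum[:, None]
            profile = extract_spectral_profile(HSICube(cube), mask)
            add(extract_hsi_traits(profile), treatment, day, "HSI")
        for day in CT_DAYS:
            shrink = 1.0 if treatment == "WW" else 0.9
            outer = 40.0 * shrink - 0.05 * (day - 84)
            inner = 25.0 * shrink - 0.10 * (day - 84)
            truth = annulus_slice(128, outer, inner, 1000.0, 0.0)
            sino = Sinogram(radon(truth, theta=np.arange(360.0)).T, 1.0)
            ct_slice = reconstruct_slice(sino)
            add(extract_ct_traits(ct_slice), treatment, day, "CT")
    return pd.concat(records, ignore_index=True)
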