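"""Synthetic imaging front end: plate rendering, segmentation, morphometry.

The real trait tables come from a proprietary top-view imaging platform
whose algorithms are not publicly described.  This module is an explicit
emulation built for end-to-end testing of the image-to-table path: it
renders synthetic top-view plate images of rosettes with known geometry,
segments plants by excess-green thresholding, and measures a small
morphometric trait set per plant.  Every operator here is invented for the
test path; the screening pipeline itself accepts phenotype tables straight
from CSV and never requires this module.

Conventions: 0-based pixel coordinates, row-major arrays; a fixed mm/px
scale is carried in the image metadata and used for all unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

__all__ = [
    "PlateImage",
    "PlantMask",
    "PlantSpec",
    "make_plate_layout",
    "render_plate",
    "segment_plants",
    "measure_traits",
]

#: Minimum region size (px) kept by segmentation; smaller specks are noise.
MIN_REGION_PX = 50

_BACKGROUND_RGB = (110, 70, 60)  # soil-like, excess-green well below 0
_EXG_THRESHOLD = 30  # on 2G - R - B in 8-bit units


@dataclass(frozen=True)
class WellLayout:
    """Well centers (px) and radius for one plate."""

    plate_id: str
    centers: tuple[tuple[float, float], ...]  # (row, col) px
    well_radius_px: float
    shape: tuple[int, int]  # image (rows, cols)
    mm_per_px: float


@dataclass(frozen=True)
class PlantSpec:
    """Target geometry of one synthetic rosette."""

    well: int  # index into layout.centers
    area_mm2: float
    lobes: int = 0  # 0 = plain disk
    greenness: float = 1.0  # scales the green channel


@dataclass
class PlateImage:
    """RGB image plus plate geometry metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    layout: WellLayout

    @property
    def mm_per_px(self) -> float:
        return self.layout.mm_per_px


@dataclass
class PlantMask:
    """Labeled plant regions and their well assignment."""

    labels: np.ndarray  # (H, W) int, 0 = background, 1..n regions
    region_wells: dict[int, int] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


def make_plate_layout(
    plate_id: str = "PL01",
    n_rows: int = 2,
    n_cols: int = 3,
    well_radius_px: float = 60.0,
    mm_per_px: float = 0.5,
    margin_px: float = 20.0,
) -> WellLayout:
    """Regular grid layout for an ``n_rows x n_cols`` well plate."""
    pitch = 2 * well_radius_px + margin_px
    centers = tuple(
        (margin_px + well_radius_px + r * pitch,
         margin_px + well_radius_px + c * pitch)
        for r in range(n_rows) for c in range(n_cols)
    )
    h = int(np.ceil(margin_px + n_rows * pitch))
    w = int(np.ceil(margin_px + n_cols * pitch))
    return WellLayout(plate_id=plate_id, centers=centers,
                      well_radius_px=well_radius_px, shape=(h, w),
                      mm_per_px=mm_per_px)


def _rosette_mask(shape: tuple[int, int], center: tuple[float, float],
                  radius_px: float, lobes: int, phase: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    dist = np.hypot(dy, dx)
    if lobes <= 0:
        return dist <= radius_px
    ang = np.arctan2(dy, dx)
    # lobed boundary keeps the same enclosed area as the plain disk:
    # r(theta) = R * sqrt(1 + a*cos(n*theta)) has mean r^2 equal to R^2
    a = 0.35
    boundary = radius_px * np.sqrt(1.0 + a * np.cos(lobes * ang + phase))
    return dist <= boundary


def render_plate(
    layout: WellLayout, plant_specs: list[PlantSpec], seed: int = 0
) -> PlateImage:
    """Render a synthetic top-view plate image (deterministic given seed).

    Plant pixels are green (high excess-green); the background is a
    soil-like brown with mild texture noise, spectrally separated from the
    plant class.  Raises if a spec references a nonexistent well.
    """
    for spec in plant_specs:
        if not 0 <= spec.well < len(layout.centers):
            raise ValueError(
                f"plant spec references well {spec.well}; plate "
                f"{layout.plate_id} has wells 0..{len(layout.centers) - 1}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4001]))
    h, w = layout.shape
    img = np.empty((h, w, 3), dtype=float)
    for ch, base in enumerate(_BACKGROUND_RGB):
        img[..., ch] = base + rng.normal(0.0, 4.0, size=(h, w))
    for spec in plant_specs:
        center = layout.centers[spec.well]
        radius_px = np.sqrt(spec.area_mm2 / np.pi) / layout.mm_per_px
        phase = rng.uniform(0, 2 * np.pi)
        mask = _rosette_mask((h, w), center, radius_px, spec.lobes, phase)
        img[mask, 0] = 40 + rng.normal(0.0, 3.0, size=mask.sum())
        img[mask, 1] = np.clip(120 + 100 * spec.greenness
                               + rng.normal(0.0, 3.0, size=mask.sum()), 0, 255)
        img[mask, 2] = 45 + rng.normal(0.0, 3.0, size=mask.sum())
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return PlateImage(pixels=pixels, layout=layout)


def segment_plants(image: PlateImage, min_size: int = MIN_REGION_PX) -> PlantMask:
    """Excess-green threshold + connected components + minimum-size filter.

    Each surviving region is assigned to the nearest well center.  An empty
    mask (blank plate) is a valid result, not an error.
    """
    px = image.pixels.astype(int)
    exg = 2 * px[..., 1] - px[..., 0] - px[..., 2]
    fg = exg > _EXG_THRESHOLD
    fg = morphology.remove_small_objects(fg, max_size=min_size - 1)
    labels = measure.label(fg, connectivity=2)
    region_wells: dict[int, int] = {}
    centers = np.array(image.layout.centers)
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        dists = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
        region_wells[region.label] = int(np.argmin(dists))
    return PlantMask(labels=labels, region_wells=region_wells)


def measure_traits(mask: PlantMask, image: PlateImage) -> pd.DataFrame:
    """Morphometric traits per segmented region, in physical units.

    Columns: region, well, area_mm2, hull_area_mm2, compactness
    (area / convex-hull area, in (0, 1]), width_mm, height_mm,
    eccentricity, mean_greenness.
    """
    scale = image.layout.mm_per_px
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("image lacks a valid mm/px scale")
    px_area_mm2 = scale ** 2
    green = image.pixels[..., 1].astype(float)
    rows = []
    for region in measure.regionprops(mask.labels):
        minr, minc, maxr, maxc = region.bbox
        rows.append({
            "region": region.label,
            "well": mask.region_wells.get(region.label, -1),
            "area_mm2": region.area * px_area_mm2,
            "hull_area_mm2": region.area_convex * px_area_mm2,
            "compactness": region.area / region.area_convex,
            "width_mm": (maxc - minc) * scale,
            "height_mm": (maxr - minr) * scale,
            "eccentricity": region.eccentricity,
            "mean_greenness": green[mask.labels == region.label].mean() / 255.0,
        })
    return pd.DataFrame(
        rows, columns=["region", "well", "area_mm2", "hull_area_mm2",
                       "compactness", "width_mm", "height_mm",
                       "eccentricity", "mean_greenness"])
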