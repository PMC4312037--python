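"""TTC histology quantification.

Viable myocardium takes up triphenyl tetrazolium chloride and photographs
brick red; infarcted tissue stays pale pink.  Tissue is separated from the
white photographic background, classified as viable or infarcted by a
saturation/luminance rule, and the per-face areas are integrated across the
1 mm slab stack (front and back faces averaged per slab) to give infarct
volume as a percentage of total myocardial volume — a ratio that cancels
tissue shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .phantom import HistologySlice

__all__ = [
    "HistologyThresholds",
    "SliceMeasurement",
    "segment_tissue",
    "classify_viability",
    "measure_slice",
    "percent_infarct_histology",
]


@dataclass(frozen=True)
class HistologyThresholds:
    """Colour-classification thresholds (unit scale).

    ``white_min``: a pixel whose darkest channel exceeds this is background
    (equivalently luminance high and chroma low: min = V * (1 - S)).
    Within tissue, ``saturation`` below ``infarct_sat_max`` together with
    luma above ``infarct_lum_min`` marks the pale TTC-negative infarct.
    """

    white_min: float = 0.84
    infarct_sat_max: float = 0.35
    infarct_lum_min: float = 0.55


@dataclass(frozen=True)
class SliceMeasurement:
    """Per-slab tissue and infarct areas on both cut faces (mm^2)."""

    tissue_area_front_mm2: float
    tissue_area_back_mm2: float
    infarct_area_front_mm2: float
    infarct_area_back_mm2: float

    def __post_init__(self):
        for inf, tis in [(self.infarct_area_front_mm2, self.tissue_area_front_mm2),
                         (self.infarct_area_back_mm2, self.tissue_area_back_mm2)]:
            if inf < 0 or inf > tis + 1e-9:
                raise ValueError("infarct area must lie in [0, tissue area]")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def segment_tissue(image: np.ndarray, pixel_size_mm: float,
                   thresholds: HistologyThresholds = HistologyThresholds()
                   ) -> np.ndarray:
    """Tissue mask: everything not matching the near-white background,
    keeping only the largest connected component."""
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    rgb = _as_float_rgb(image)
    background = rgb.min(axis=2) > thresholds.white_min
    tissue = ~background
    if not tissue.any():
        raise ValueError("no tissue found: image is blank/background only")
    comp = measure.label(tissue, connectivity=1)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == sizes.argmax()


def classify_viability(image: np.ndarray, tissue_mask: np.ndarray,
                       thresholds: HistologyThresholds = HistologyThresholds()
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Partition the tissue mask into (viable, infarct) by colour.

    Pale-pink TTC-negative infarct: low saturation and high luma; the deep
    red viable stain fails both.  The two returned masks partition the
    tissue mask exactly.
    """
    if not np.asarray(tissue_mask).any():
        raise ValueError("tissue mask is empty")
    rgb = _as_float_rgb(image)
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    infarct = tissue_mask & (sat < thresholds.infarct_sat_max) \
        & (luma > thresholds.infarct_lum_min)
    viable = tissue_mask & ~infarct
    return viable, infarct


def measure_slice(hslice: HistologySlice,
                  thresholds: HistologyThresholds = HistologyThresholds()
                  ) -> SliceMeasurement:
    """Segment both faces of one slab and report areas in mm^2."""
    areas = {}
    for name, img in [("front", hslice.front_image), ("back", hslice.back_image)]:
        tissue = segment_tissue(img, hslice.pixel_size_mm, thresholds)
        _, infarct = classify_viability(img, tissue, thresholds)
        px = hslice.pixel_size_mm ** 2
        areas[name] = (float(tissue.sum() * px), float(infarct.sum() * px))
    return SliceMeasurement(
        tissue_area_front_mm2=areas["front"][0],
        tissue_area_back_mm2=areas["back"][0],
        infarct_area_front_mm2=areas["front"][1],
        infarct_area_back_mm2=areas["back"][1])


def percent_infarct_histology(slices: list[SliceMeasurement],
                              thickness_mm: float) -> float:
    """Infarct volume as a percentage of total myocardial volume.

    Each slab contributes (front + back area)/2 * thickness to both the
    infarct and tissue volume sums (trapezoid-like front/back averaging,
    matching the ~500 um effective out-of-plane resolution of photographing
    both faces of 1 mm slabs).
    """
    if not slices:
        raise ValueError("at least one slice measurement is required")
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be positive")
    infarct = sum((s.infarct_area_front_mm2 + s.infarct_area_back_mm2) / 2.0
                  for s in slices) * thickness_mm
    tissue = sum((s.tissue_area_front_mm2 + s.tissue_area_back_mm2) / 2.0
                 for s in slices) * thickness_mm
    if tissue <= 0:
        raise ValueError("total tissue volume is zero")
    return 100.0 * infarct / tissue
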