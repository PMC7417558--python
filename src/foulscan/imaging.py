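"""Panel-photograph coverage quantification and biomass per area.

Reproduces an ImageJ-style workflow: maximum intensity projection of an
image stack, conversion to 8-bit grayscale, Otsu (or fixed) thresholding
to a binary fouling mask, removal of small particles, and percent cover
within a region of interest.  Biomass is wet panel weight minus the clean
panel weight, divided by the effective panel area (336 cm^2 by default: a
20 x 20 cm panel minus four 16 cm^2 carabiner attachment areas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "PanelImageStack",
    "CoverageParams",
    "BiomassRecord",
    "DEFAULT_PANEL_AREA_CM2",
    "max_intensity_projection",
    "to_gray8",
    "binarize_and_clean",
    "coverage_percent",
    "biomass_per_area",
    "measure_stack",
]

DEFAULT_PANEL_AREA_CM2 = 336.0


@dataclass
class PanelImageStack:
    pixels: np.ndarray  # depth x height x width
    roi: Optional[Tuple[int, int, int, int]] = None  # (x0, y0, x1, y1), half-open
    true_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a depth x height x width array, depth >= 1")
        if self.roi is not None:
            x0, y0, x1, y1 = self.roi
            _, h, w = self.pixels.shape
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"roi {self.roi} outside image bounds {(w, h)}")


@dataclass(frozen=True)
class CoverageParams:
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: Optional[int] = None
    polarity: str = "bright_is_fouling"  # or "dark_is_fouling"
    min_particle_px: int = 5

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        if self.threshold_method == "otsu" and self.fixed_threshold is not None:
            raise ValueError("fixed_threshold only applies to the fixed method")
        if self.polarity not in ("bright_is_fouling", "dark_is_fouling"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class BiomassRecord:
    wet_weight: float
    clean_panel_weight: float
    effective_area: float
    biomass_per_area: float


def max_intensity_projection(stack) -> np.ndarray:
    """Per-pixel maximum across slices; a depth-1 stack is returned as is."""
    pixels = stack.pixels if isinstance(stack, PanelImageStack) else np.asarray(stack)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3 or pixels.shape[0] < 1:
        raise ValueError("expected a non-empty depth x height x width stack")
    return pixels.max(axis=0)


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Convert to 8-bit grayscale.

    Multichannel input (H x W x C) is averaged across channels; higher bit
    depths are linearly rescaled from their full range to 0-255 with
    round-half-up.  8-bit grayscale input is returned unchanged.
    """
    img = np.asarray(image)
    src_dtype = img.dtype
    if img.ndim == 3:
        img = img.astype(np.float64).mean(axis=2)
    elif img.ndim != 2:
        raise ValueError("expected a 2-D image, optionally with channels")
    if src_dtype == np.uint8:
        if img.dtype == np.uint8:
            return img.copy()
        scaled = img  # channel mean of 8-bit data, already on the 0-255 scale
    elif np.issubdtype(src_dtype, np.floating):
        scaled = img * 255.0  # unit-range floats
    else:
        info = np.iinfo(src_dtype)
        scaled = img.astype(np.float64) * (255.0 / info.max)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold from the 256-bin histogram of an 8-bit image."""
    return int(threshold_otsu(image, nbins=256))


def binarize_and_clean(
    image: np.ndarray, params: CoverageParams = CoverageParams()
) -> np.ndarray:
    """Threshold an 8-bit image and drop particles below the minimum size.

    Foreground is ``pixel > threshold`` for bright fouling and
    ``pixel <= threshold`` for dark fouling.  Connected components
    (8-connectivity) with fewer than ``min_particle_px`` pixels are
    removed.  A constant image under Otsu falls back to a fixed midpoint
    threshold of 128 with a warning.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("binarize_and_clean expects an 8-bit image")
    if params.threshold_method == "fixed":
        thr = int(params.fixed_threshold)
    else:
        if img.min() == img.max():
            warnings.warn("constant image: Otsu undefined, using fixed threshold 128")
            thr = 128
        else:
            thr = otsu_threshold(img)
    if params.polarity == "bright_is_fouling":
        mask = img > thr
    else:
        mask = img <= thr
    if params.min_particle_px > 1:
        labels = label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = sizes >= params.min_particle_px  # components below the minimum go
        mask = keep[labels]
    return mask


def coverage_percent(
    mask: np.ndarray, roi: Optional[Tuple[int, int, int, int]] = None
) -> float:
    """Percent foreground within the region of interest (whole mask if
    roi is None).  ROI is (x0, y0, x1, y1), 0-based, half-open."""
    mask = np.asarray(mask, dtype=bool)
    if roi is not None:
        x0, y0, x1, y1 = roi
        h, w = mask.shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"roi {roi} invalid for mask of shape {(w, h)}")
        mask = mask[y0:y1, x0:x1]
    if mask.size == 0:
        raise ValueError("empty region of interest")
    return 100.0 * mask.sum() / mask.size


def biomass_per_area(
    wet_weight: float,
    clean_panel_weight: float,
    effective_area: float = DEFAULT_PANEL_AREA_CM2,
) -> BiomassRecord:
    """Fouling biomass per panel area in g/cm^2."""
    if effective_area <= 0:
        raise ValueError("effective_area must be positive")
    if wet_weight < 0 or clean_panel_weight < 0:
        raise ValueError("weights must be non-negative")
    diff = wet_weight - clean_panel_weight
    if diff < 0:
        warnings.warn(
            "wet weight below clean panel weight; clipping biomass to zero"
        )
        diff = 0.0
    return BiomassRecord(
        wet_weight=wet_weight,
        clean_panel_weight=clean_panel_weight,
        effective_area=effective_area,
        biomass_per_area=diff / effective_area,
    )


def measure_stack(
    stack: PanelImageStack, params: CoverageParams = CoverageParams()
) -> float:
    """Full pipeline on one stack: MIP -> 8-bit -> binarize/clean ->
    percent cover within the stack's ROI."""
    mip = max_intensity_projection(stack)
    gray = to_gray8(mip)
    mask = binarize_and_clean(gray, params)
    return coverage_percent(mask, stack.roi)
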