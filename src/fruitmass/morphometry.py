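"""Metric morphometry: reference-square calibration and L/D extraction.

L is the maximum extent of the fruit mask along its moments-derived major
axis; D is the maximum extent along the perpendicular (equatorial) axis.
Extents are measured on pixel centers with a +1 px end-correction so an
n-pixel run has extent n, then scaled to millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from fruitmass.errors import CalibrationError, SegmentationError
from fruitmass.segmentation import LabeledMask, segment


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-millimetre conversion factor."""

    mm_per_px: float
    source: str = ""

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


@dataclass(frozen=True)
class FruitMorphometry:
    """Measured fruit dimensions (mm) and mask statistics."""

    length_mm: float
    diameter_mm: float
    orientation_deg: float
    area_px: int

    def __post_init__(self):
        if not (self.length_mm >= self.diameter_mm > 0):
            raise ValueError("need length_mm >= diameter_mm > 0")


def compute_scale(
    calibration_image: np.ndarray,
    square_side_mm: float = 10.0,
    source: str = "",
) -> CalibrationScale:
    """Estimate mm/px from an image of a dark reference square.

    The square is segmented by thresholding grayscale intensity midway
    between the image extremes; its side is the mean of the row-wise and
    column-wise extents of the largest dark component.
    """
    img = np.asarray(calibration_image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    img = img.astype(float)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-6:
        raise CalibrationError("flat image: no square found")
    dark = img < 0.5 * (lo + hi)
    comp = skmeasure.label(dark, connectivity=2)
    if comp.max() == 0:
        raise CalibrationError("no dark region found")
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    square = comp == sizes.argmax()
    if square[0, :].any() or square[-1, :].any() or square[:, 0].any() or square[:, -1].any():
        raise CalibrationError("reference square touches the image border")
    rows, cols = np.nonzero(square)
    row_widths = np.bincount(rows)[np.unique(rows)]
    col_heights = np.bincount(cols)[np.unique(cols)]
    side_px = 0.5 * (row_widths.mean() + col_heights.mean())
    return CalibrationScale(mm_per_px=square_side_mm / side_px, source=source)


def extract_dimensions(
    mask: LabeledMask | np.ndarray, scale: CalibrationScale
) -> FruitMorphometry:
    """Measure L (major-axis extent) and D (equatorial extent) of a mask."""
    m = mask.mask if isinstance(mask, LabeledMask) else np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        raise SegmentationError("empty mask")
    x = xs.astype(float)
    y = ys.astype(float)
    mu20 = np.var(x)
    mu02 = np.var(y)
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        theta = 0.0  # near-circular: fall back to image axes
    else:
        theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    u = x * cos_t + y * sin_t
    v = -x * sin_t + y * cos_t
    len_u = float(u.max() - u.min() + 1.0)
    len_v = float(v.max() - v.min() + 1.0)
    if len_v > len_u:
        len_u, len_v = len_v, len_u
        theta += 0.5 * np.pi
    orient = np.rad2deg(theta)
    orient = (orient + 90.0) % 180.0 - 90.0  # normalize to (-90, 90]
    return FruitMorphometry(
        length_mm=len_u * scale.mm_per_px,
        diameter_mm=len_v * scale.mm_per_px,
        orientation_deg=float(orient),
        area_px=int(ys.size),
    )


def measure_image(
    image: np.ndarray,
    scale: CalibrationScale,
    seed: int = 0,
    **segment_kwargs,
) -> FruitMorphometry:
    """Segment a single-fruit image and extract its metric dimensions."""
    mask = segment(image, seed=seed, **segment_kwargs)
    return extract_dimensions(mask, scale)
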