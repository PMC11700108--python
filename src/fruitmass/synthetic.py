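"""Synthetic fruit cohorts and rendered single-fruit images with ground truth.

Tabular cohorts draw correlated (L, D) pairs from a truncated bivariate
normal and generate weight through a configurable allometric law plus
Gaussian noise. Image rendering produces a single (super)elliptical fruit on
a near-white stage, with optional illumination gradient and sensor noise, and
returns the exact foreground mask as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict

import numpy as np
import pandas as pd

from fruitmass._rng import substream
from fruitmass.errors import FrameFitError, SamplingError, SpecError
from fruitmass.models.forms import FORM_BASIS

COHORT_COLUMNS = ("length_mm", "diameter_mm", "weight_g")

# Retry budget multiplier for rejection truncation.
_REJECTION_BUDGET = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for one synthetic fruit cohort.

    Lengths/diameters are drawn from a correlated bivariate normal with the
    given moments, rejection-truncated to [L_min, L_max] x [D_min, D_max].
    Weight is gen_a + gen_b * f(L, D) + N(0, noise_sd), clipped below at
    fw_floor, where f is selected by ``gen_form``.
    """

    name: str
    n: int
    L_mean: float
    L_sd: float
    D_mean: float
    D_sd: float
    L_min: float
    L_max: float
    D_min: float
    D_max: float
    rho_LD: float = 0.8
    gen_form: str = "LD"
    gen_a: float = 0.0
    gen_b: float = 1.0
    noise_sd: float = 0.0
    fw_floor: float = 0.05

    def __post_init__(self):
        if self.n < 2:
            raise SpecError("cohort size must be >= 2")
        if self.L_sd <= 0 or self.D_sd <= 0:
            raise SpecError("standard deviations must be positive")
        if not (self.L_min < self.L_mean < self.L_max):
            raise SpecError("need L_min < L_mean < L_max")
        if not (self.D_min < self.D_mean < self.D_max):
            raise SpecError("need D_min < D_mean < D_max")
        if not abs(self.rho_LD) < 1:
            raise SpecError("|rho_LD| must be < 1")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.fw_floor <= 0:
            raise SpecError("fw_floor must be > 0")
        if self.gen_form not in FORM_BASIS:
            raise SpecError(f"unknown generating form {self.gen_form!r}")


def generate_tabular_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Sample a cohort of (length_mm, diameter_mm, weight_g) records.

    Deterministic for fixed (spec, seed). Raises SamplingError if rejection
    truncation exhausts its budget (infeasible bounds).
    """
    rng = substream(seed, f"cohort:{spec.name}")
    cov = np.array(
        [
            [spec.L_sd**2, spec.rho_LD * spec.L_sd * spec.D_sd],
            [spec.rho_LD * spec.L_sd * spec.D_sd, spec.D_sd**2],
        ]
    )
    mean = np.array([spec.L_mean, spec.D_mean])
    kept_L: list[np.ndarray] = []
    kept_D: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    budget = _REJECTION_BUDGET * spec.n
    while n_kept < spec.n:
        batch = min(max(spec.n - n_kept, 256) * 2, budget - n_drawn)
        if batch <= 0:
            raise SamplingError(
                f"rejection budget exhausted after {n_drawn} draws "
                f"({n_kept}/{spec.n} accepted); truncation bounds look infeasible"
            )
        draws = rng.multivariate_normal(mean, cov, size=batch, method="cholesky")
        n_drawn += batch
        ok = (
            (draws[:, 0] >= spec.L_min)
            & (draws[:, 0] <= spec.L_max)
            & (draws[:, 1] >= spec.D_min)
            & (draws[:, 1] <= spec.D_max)
        )
        acc = draws[ok]
        kept_L.append(acc[:, 0])
        kept_D.append(acc[:, 1])
        n_kept += acc.shape[0]
    L = np.concatenate(kept_L)[: spec.n]
    D = np.concatenate(kept_D)[: spec.n]
    fw = spec.gen_a + spec.gen_b * FORM_BASIS[spec.gen_form](L, D)
    if spec.noise_sd > 0:
        fw = fw + rng.normal(0.0, spec.noise_sd, size=spec.n)
    fw = np.maximum(fw, spec.fw_floor)
    return pd.DataFrame({"length_mm": L, "diameter_mm": D, "weight_g": fw})


@dataclass(frozen=True)
class FruitGroundTruth:
    """True dimensions and appearance class of one rendered fruit."""

    L_mm: float
    D_mm: float
    orientation_deg: float = 0.0
    hue_class: str = "green"

    def __post_init__(self):
        if not (self.L_mm >= self.D_mm > 0):
            raise SpecError("need L_mm >= D_mm > 0")
        if self.hue_class not in _HUE_BASE:
            raise SpecError(f"unknown hue class {self.hue_class!r}")


@dataclass(frozen=True)
class ImagingSpec:
    """Virtual camera / stage parameters for rendering."""

    image_width_px: int = 400
    image_height_px: int = 400
    mm_per_px: float = 0.1
    background_gray: float = 0.92
    illumination_gradient: float = 0.0
    sensor_noise_sd: float = 0.0
    include_calibration_square: bool = True
    square_side_mm: float = 10.0

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise SpecError("mm_per_px must be positive")
        if self.image_width_px < 8 or self.image_height_px < 8:
            raise SpecError("frame too small")
        if not (0 < self.background_gray <= 1):
            raise SpecError("background_gray must be in (0, 1]")
        if self.sensor_noise_sd < 0:
            raise SpecError("sensor_noise_sd must be >= 0")


@dataclass
class RenderResult:
    """A rendered image plus its ground-truth manifest and exact mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, true foreground
    manifest: Dict = field(default_factory=dict)


# Base RGB colors (in [0,1]) per fruit hue class.
_HUE_BASE = {
    "green": (0.28, 0.58, 0.22),
    "yellow": (0.88, 0.78, 0.20),
    "red": (0.72, 0.14, 0.16),
}


def _pixel_grid(imaging: ImagingSpec):
    h, w = imaging.image_height_px, imaging.image_width_px
    y, x = np.mgrid[0:h, 0:w]
    return x + 0.5, y + 0.5  # pixel centers


def render_fruit_image(
    truth: FruitGroundTruth,
    imaging: ImagingSpec,
    seed: int = 0,
    superellipse_exponent: float = 2.0,
) -> RenderResult:
    """Render a top view of one (super)elliptical fruit.

    The fruit footprint is a superellipse with full axes (L_mm, D_mm) at the
    given orientation, centered in the frame; exponent 2 gives an ellipse.
    Radial shading darkens the rim, so the fruit is chromatically distinct
    from the uniform light background even before noise.
    """
    a = 0.5 * truth.L_mm / imaging.mm_per_px  # semi-major, px
    b = 0.5 * truth.D_mm / imaging.mm_per_px
    h, w = imaging.image_height_px, imaging.image_width_px
    cx, cy = w / 2.0, h / 2.0
    reach = max(a, b)
    if cx - reach < 1 or cx + reach > w - 1 or cy - reach < 1 or cy + reach > h - 1:
        raise FrameFitError(
            f"fruit (semi-axes {a:.1f}x{b:.1f} px) does not fit the {w}x{h} frame"
        )

    x, y = _pixel_grid(imaging)
    theta = np.deg2rad(truth.orientation_deg)
    u = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    v = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    p = superellipse_exponent
    radial = (np.abs(u) / a) ** p + (np.abs(v) / b) ** p
    mask = radial <= 1.0

    img = np.full((h, w, 3), imaging.background_gray, dtype=float)
    base = np.array(_HUE_BASE[truth.hue_class])
    shade = 1.0 - 0.30 * np.clip(radial, 0.0, 1.0)  # rim darkening
    img[mask] = base[None, :] * shade[mask, None]

    if imaging.illumination_gradient:
        fall = 1.0 - imaging.illumination_gradient * (x / max(w - 1, 1))
        img *= fall[..., None]
    rng = substream(seed, "render")
    if imaging.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, imaging.sensor_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    image_u8 = np.round(img * 255.0).astype(np.uint8)

    manifest = {
        "truth": asdict(truth),
        "mm_per_px": imaging.mm_per_px,
        "imaging": asdict(imaging),
        "seed": seed,
        "superellipse_exponent": superellipse_exponent,
        "area_px": int(mask.sum()),
    }
    return RenderResult(image=image_u8, mask=mask, manifest=manifest)


def render_calibration_image(imaging: ImagingSpec, antialias: bool = False) -> np.ndarray:
    """Render the reference image: a black square of known metric side.

    The square (side ``square_side_mm``) is centered on the light stage. With
    ``antialias`` the per-pixel coverage of the square is used as darkness,
    producing soft 1-px edges; otherwise pixels are binarized at 50% coverage.
    """
    side_px = imaging.square_side_mm / imaging.mm_per_px
    h, w = imaging.image_height_px, imaging.image_width_px
    if side_px > min(h, w) - 4:
        raise FrameFitError(f"calibration square ({side_px:.0f} px) does not fit frame")
    cx, cy = w / 2.0, h / 2.0
    half = side_px / 2.0

    def overlap(centers, lo, hi):
        # overlap length of unit pixel cell [c-0.5, c+0.5] with [lo, hi]
        return np.clip(np.minimum(centers + 0.5, hi) - np.maximum(centers - 0.5, lo), 0.0, 1.0)

    x, y = _pixel_grid(imaging)
    cov = overlap(x, cx - half, cx + half) * overlap(y, cy - half, cy + half)
    if not antialias:
        cov = (cov >= 0.5).astype(float)
    img = imaging.background_gray * (1.0 - cov)
    image = np.repeat(np.round(np.clip(img, 0, 1) * 255.0).astype(np.uint8)[..., None], 3, axis=2)
    return image


# ---------------------------------------------------------------------------
# Bundled cohort recipes
# ---------------------------------------------------------------------------
# Five plum cohorts (one 2019 development cohort, four 2021 genotype cohorts)
# whose dimension moments, bounds and sizes mirror the published descriptive
# statistics of the study's field data; weights are generated with the
# best-fitting allometric law reported for each cohort.

DEFAULT_COHORTS: Dict[str, CohortSpec] = {
    "plum-2019": CohortSpec(
        name="plum-2019", n=1028,
        L_mean=25.74, L_sd=1.64, L_min=21.13, L_max=32.22,
        D_mean=24.50, D_sd=1.84, D_min=19.17, D_max=30.55,
        rho_LD=0.8, gen_form="LD", gen_a=-4.4940, gen_b=0.0225,
        noise_sd=0.5,
    ),
    "gavali-2021": CohortSpec(
        name="gavali-2021", n=518,
        L_mean=26.11, L_sd=1.96, L_min=20.44, L_max=30.88,
        D_mean=25.73, D_sd=2.01, D_min=18.58, D_max=30.80,
        rho_LD=0.8, gen_form="LD2", gen_a=0.1243, gen_b=0.0005,
        noise_sd=0.40,
    ),
    "ghandi-2021": CohortSpec(
        name="ghandi-2021", n=508,
        L_mean=22.44, L_sd=2.06, L_min=15.92, L_max=26.97,
        D_mean=21.95, D_sd=2.11, D_min=16.03, D_max=27.07,
        rho_LD=0.8, gen_form="LD2", gen_a=-0.0388, gen_b=0.0006,
        noise_sd=0.33,
    ),
    "shahryari-2021": CohortSpec(
        name="shahryari-2021", n=530,
        L_mean=23.58, L_sd=2.31, L_min=16.74, L_max=29.22,
        D_mean=21.78, D_sd=2.55, D_min=13.29, D_max=28.33,
        rho_LD=0.8, gen_form="LD2", gen_a=-0.0132, gen_b=0.0006,
        noise_sd=0.40,
    ),
    "jangali-2021": CohortSpec(
        name="jangali-2021", n=486,
        L_mean=15.12, L_sd=1.19, L_min=11.15, L_max=19.00,
        D_mean=13.52, D_sd=1.19, D_min=8.22, D_max=16.66,
        rho_LD=0.8, gen_form="LD2", gen_a=-0.0375, gen_b=0.0005,
        noise_sd=0.085,
    ),
}
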