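"""Chroma-based fruit segmentation.

Chain: RGB -> CIELAB (sRGB/D65), 2-cluster K-means on the (a*, b*) chroma
channels only (lightness is excluded so smooth illumination changes do not
move the boundary), border-majority background selection, then morphological
cleanup (opening with a disk element, hole filling, largest component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from fruitmass._rng import substream
from fruitmass.errors import DegenerateImageError, SegmentationError

_KMEANS_MAX_ITER = 300
# restarts: farthest-point + seeded random restarts on large inputs;
# instances with few distinct chroma values restart from all point pairs
_KMEANS_N_INIT_LARGE = 4
_KMEANS_SMALL_N = 64


@dataclass
class LabeledMask:
    """Binary fruit mask with clustering provenance."""

    mask: np.ndarray  # (H, W) bool, fruit = True
    cluster_labels: np.ndarray  # (H, W) int in {0, 1}
    steps_applied: List[str] = field(default_factory=list)

    def validate(self) -> None:
        n_comp = skmeasure.label(self.mask, connectivity=2).max()
        if n_comp != 1:
            raise SegmentationError(f"mask has {n_comp} components, expected 1")
        m = self.mask
        if m[0, :].any() and m[-1, :].any() and m[:, 0].any() and m[:, -1].any():
            raise SegmentationError("foreground touches all four borders")


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to CIELAB (sRGB primaries, D65 white).

    Accepts uint8 in [0, 255] or float in [0, 1]; returns an (H, W, 3) float
    array with L* in [0, 100].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        image = image.astype(float) / 255.0
    else:
        image = image.astype(float)
        if image.max() > 1.0 + 1e-9:
            raise ValueError("float images must be scaled to [0, 1]")
    return skcolor.rgb2lab(image)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> Tuple[np.ndarray, np.ndarray, float]:
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)  # argmin breaks ties toward lower index
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(centers.shape[0]):
            sel = labels == j
            if sel.any():
                centers[j] = X[sel].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-served point
                centers[j] = X[d2.min(axis=1).argmax()]
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centers, wcss


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(X.shape[0])]]
    for _ in range(1, k):
        d2 = np.min(
            [((X - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        centers.append(X[int(d2.argmax())])
    return np.array(centers, dtype=float)


def cluster_ab(lab: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """K-means (Lloyd) on the per-pixel (a*, b*) chroma vectors.

    Runs a farthest-point initialization plus a few seeded random restarts
    and keeps the partition with the lowest within-cluster sum of squares;
    deterministic for a fixed seed. Returns an (H, W) integer label image.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) Lab image")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = lab[..., 1:].reshape(-1, 2)
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] < k:
        raise DegenerateImageError(
            f"image has {uniq.shape[0]} distinct chroma values, need >= {k}"
        )
    rng = substream(seed, "kmeans")
    inits = [_farthest_point_init(X, k, rng)]
    if k == 2 and uniq.shape[0] <= _KMEANS_SMALL_N and X.shape[0] <= 4096:
        # tiny instance: restart from every distinct pair of unique points,
        # which empirically attains the exhaustive-search optimum
        inits += [
            uniq[[i, j]].astype(float).copy()
            for i in range(uniq.shape[0])
            for j in range(i + 1, uniq.shape[0])
        ]
    else:
        for _ in range(_KMEANS_N_INIT_LARGE - 1):
            idx = rng.choice(uniq.shape[0], size=k, replace=False)
            inits.append(uniq[idx].astype(float).copy())
    best = None
    for centers in inits:
        labels, centers, wcss = _lloyd(X, centers, _KMEANS_MAX_ITER)
        if best is None or wcss < best[2] - 1e-12:
            best = (labels, centers, wcss)
    labels = best[0]
    return labels.reshape(lab.shape[:2])


def select_fruit_cluster(labels: np.ndarray) -> LabeledMask:
    """Declare the border-majority cluster background, the other fruit."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size != 2:
        raise SegmentationError(
            f"expected exactly 2 clusters, found {present.size}"
        )
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[1:-1, 0], labels[1:-1, -1]]
    )
    counts = np.array([(border == lab).sum() for lab in present])
    background = present[int(counts.argmax())]
    fruit = present[present != background][0]
    mask = labels == fruit
    if not mask.any():
        raise SegmentationError("fruit cluster is empty")
    return LabeledMask(
        mask=mask,
        cluster_labels=labels.astype(int),
        steps_applied=["cluster_ab", "select_fruit_cluster"],
    )


def refine_mask(
    mask: LabeledMask | np.ndarray,
    disk_radius_px: int = 5,
    cleanup: str = "opening",
) -> LabeledMask:
    """Morphological cleanup: opening (or closing), hole fill, largest blob.

    ``cleanup`` selects the standard operator: "opening" (erosion then
    dilation, the default) or "closing" (dilation then erosion).
    """
    if isinstance(mask, LabeledMask):
        m = mask.mask
        labels = mask.cluster_labels
        steps = list(mask.steps_applied)
    else:
        m = np.asarray(mask, dtype=bool)
        labels = m.astype(int)
        steps = []
    selem = skmorph.disk(disk_radius_px)
    if cleanup == "opening":
        m2 = skmorph.opening(m, selem).astype(bool)
    elif cleanup == "closing":
        m2 = skmorph.closing(m, selem).astype(bool)
    else:
        raise ValueError(f"unknown cleanup mode {cleanup!r}")
    if not m2.any():
        raise SegmentationError("mask empty after morphological cleanup")
    m2 = ndi.binary_fill_holes(m2)
    comp = skmeasure.label(m2, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    m2 = comp == sizes.argmax()
    out = LabeledMask(
        mask=m2,
        cluster_labels=labels,
        steps_applied=steps + [f"{cleanup}(disk r={disk_radius_px})", "fill_holes", "largest_component"],
    )
    out.validate()
    return out


def segment(
    image: np.ndarray,
    seed: int = 0,
    disk_radius_px: int = 5,
    cleanup: str = "opening",
) -> LabeledMask:
    """Full segmentation chain for a single-fruit image."""
    lab = rgb_to_lab(image)
    labels = cluster_ab(lab, k=2, seed=seed)
    pre = select_fruit_cluster(labels)
    return refine_mask(pre, disk_radius_px=disk_radius_px, cleanup=cleanup)
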