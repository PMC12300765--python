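"""Nucleus segmentation on H&E-like images and Dice-based evaluation.

Hematoxylin renders nuclei dark against a bright eosin background, so
nuclei are separated by intensity: optional Gaussian smoothing, a
global threshold that discards bright background, 2-cluster k-means on
the remaining intensities (the darker cluster is nuclear), morphological
closing and dilation, connected-component labeling, and removal of
components below a minimum pixel count. This is a deliberately compact
intensity pipeline driven by the empirically optimized parameter set of
the original detector; gland and surface-epithelium segmentation are
out of scope.

Segmentation quality is scored with the Dice similarity coefficient in
two forms: count-based, DSC = 2*TP / (2*TP + FP + FN), from detected /
manually annotated / missed cell counts; and pixel-based,
2|A∩B| / (|A| + |B|), between binary masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.color import rgb2gray
from skimage.filters import gaussian
from sklearn.cluster import KMeans

from .morphometry import PixelResolution


@dataclass(frozen=True)
class SegmentationParams:
    """Empirically optimized nucleus-detection parameters.

    ``mask_x_um``/``mask_y_um`` give the smoothing mask extent in μm
    (converted to pixels via the slide resolution and rounded to the
    nearest odd integer); ``global_threshold`` is the 0-255 intensity
    above which pixels are background; components smaller than
    ``min_nucleus_pixel_count`` pixels are dropped.
    """

    gauss_filter: bool = True
    mask_x_um: float = 5.76
    mask_y_um: float = 5.76
    global_threshold: int = 240
    min_nucleus_pixel_count: int = 250
    dilate_mask_size: int = 5
    dilate_iteration: int = 1
    close_iteration: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.global_threshold <= 255:
            raise ValueError("global_threshold must be in [0, 255]")
        for name in ("mask_x_um", "mask_y_um", "dilate_mask_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DSCReport:
    """Count-based segmentation evaluation for one sample."""

    detected: int
    manual: int
    missed: int
    false_positives: int
    dsc: float

    def __post_init__(self) -> None:
        if self.missed > self.manual:
            raise ValueError("missed cannot exceed manual")
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError("dsc must be in [0, 1]")

    @property
    def dsc_display(self) -> float:
        """DSC rounded to 3 decimals, the report display convention."""
        return round(self.dsc, 3)


def _odd_px(extent_um: float, res_um_per_px: float) -> int:
    """Convert a μm mask extent to the nearest odd pixel count (>= 1)."""
    px = max(1, round(extent_um / res_um_per_px))
    return px if px % 2 == 1 else px + 1


def _to_gray_u8(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        image = rgb2gray(image[..., :3]) * 255.0
    img = np.asarray(image, dtype=float)
    if img.max() <= 1.0 and img.min() >= 0.0 and image.dtype.kind == "f":
        img = img * 255.0
    return np.clip(img, 0, 255)


def segment_nuclei(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    res: PixelResolution = PixelResolution(0.24, 0.24),
    seed: int = 0,
) -> np.ndarray:
    """Label nuclei in a grayscale or RGB image; returns an int32 mask.

    Background 0; nuclei numbered from 1. Deterministic for a fixed
    ``seed`` (k-means initialization). A blank image — all pixels above
    the global threshold — yields an empty mask.
    """
    if image.size == 0:
        raise ValueError("image is empty")
    p = params if params is not None else SegmentationParams()
    img = _to_gray_u8(image)

    if p.gauss_filter:
        # mask extent ~ 4 sigma support per axis
        sigma_y = _odd_px(p.mask_y_um, res.res_y) / 4.0
        sigma_x = _odd_px(p.mask_x_um, res.res_x) / 4.0
        img = np.clip(gaussian(img, sigma=(sigma_y, sigma_x), preserve_range=True), 0, 255)

    foreground = img <= p.global_threshold
    if not foreground.any():
        return np.zeros(img.shape, dtype=np.int32)

    values = img[foreground].reshape(-1, 1)
    if float(values.min()) == float(values.max()):
        nuclei = foreground  # single intensity: everything below threshold is nuclear
    else:
        km = KMeans(n_clusters=2, n_init=1, random_state=seed).fit(values)
        dark_cluster = int(np.argmin(km.cluster_centers_.ravel()))
        nuclei = np.zeros(img.shape, dtype=bool)
        nuclei[foreground] = km.labels_ == dark_cluster

    for _ in range(p.close_iteration):
        nuclei = morphology.closing(nuclei, footprint=morphology.footprint_rectangle((3, 3)))
    dil = morphology.footprint_rectangle((p.dilate_mask_size, p.dilate_mask_size))
    for _ in range(p.dilate_iteration):
        nuclei = morphology.dilation(nuclei, footprint=dil)

    labels = measure.label(nuclei, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < p.min_nucleus_pixel_count)
    mask = np.isin(labels, small[small > 0])
    labels[mask] = 0
    # relabel consecutively so labels are 1..n
    return measure.label(labels > 0, connectivity=2).astype(np.int32)


def count_based_dsc(detected: int, manual: int, missed: int) -> DSCReport:
    """Dice coefficient from detected/manual/missed cell counts.

    TP = manual - missed; FP = detected - TP (must be >= 0);
    DSC = 2*TP / (2*TP + FP + FN) with FN = missed. Full precision is
    kept in ``dsc``; ``dsc_display`` rounds to 3 decimals.
    """
    if detected < 0 or manual < 0 or missed < 0:
        raise ValueError("counts must be >= 0")
    if missed > manual:
        raise ValueError("missed cannot exceed manual")
    tp = manual - missed
    fp = detected - tp
    if fp < 0:
        raise ValueError(
            f"inconsistent counts: detected ({detected}) < true positives ({tp})"
        )
    denom = 2 * tp + fp + missed
    dsc = 1.0 if denom == 0 else 2.0 * tp / denom
    return DSCReport(detected=detected, manual=manual, missed=missed,
                     false_positives=fp, dsc=dsc)


def pixel_dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Pixel-overlap Dice: 2|A∩B| / (|A| + |B|); 1.0 when both empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
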