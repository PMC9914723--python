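"""Label-artifact removal and the five enhancement combinations.

The enhancement operators are median filtering (MF, impulse-noise
smoothing), contrast-limited adaptive histogram equalisation (CLAHE) and
unsharp masking (USM, edge sharpening). The five study combinations are
CLAHE alone, MF&CLAHE, MF&USM, CLAHE&USM and MF&CLAHE&USM; operators are
applied in name order (smooth -> contrast -> sharpen). All operators map
[0, 255] into [0, 255], preserve shape, and use reflective edge handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, morphology

from .mias_io import GrayImage

__all__ = [
    "FilterParams",
    "COMBOS",
    "NoBreastRegionError",
    "remove_label",
    "median_filter",
    "clahe",
    "unsharp_mask",
    "apply_combo",
]

#: the five legal combinations, in operator application order
COMBOS: dict[str, tuple[str, ...]] = {
    "CLAHE": ("clahe",),
    "MF_CLAHE": ("mf", "clahe"),
    "MF_USM": ("mf", "usm"),
    "CLAHE_USM": ("clahe", "usm"),
    "MF_CLAHE_USM": ("mf", "clahe", "usm"),
}


class NoBreastRegionError(ValueError):
    """Morphological opening left no foreground to call the breast."""


@dataclass
class FilterParams:
    """Operator parameters. None of these are dictated by the study design;
    each default is the common practitioner choice and every value is
    echoed into run reports."""

    median_kernel: int = 3
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    usm_radius: float = 2.0
    usm_amount: float = 1.0
    label_threshold: Optional[int] = None  # None -> Otsu
    morph_radius: int = 5

    def violations(self) -> list[str]:
        errs = []
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            errs.append("median_kernel must be odd and >= 1")
        if self.clahe_clip <= 0:
            errs.append("clahe_clip must be > 0")
        if self.usm_radius <= 0:
            errs.append("usm_radius must be > 0")
        if self.usm_amount < 0:
            errs.append("usm_amount must be >= 0")
        if self.morph_radius < 1:
            errs.append("morph_radius must be >= 1")
        return errs


def _check_uint8(img: GrayImage) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img


def remove_label(img: GrayImage, p: FilterParams = FilterParams()) -> tuple[GrayImage, np.ndarray]:
    """Suppress the bright acquisition label and everything off the breast.

    Binarise at ``label_threshold`` (Otsu by default), open with a disk of
    ``morph_radius`` to delete small marks, keep the largest connected
    foreground component as the breast mask, and zero the image outside it.
    The label rectangle, being disconnected from the breast, is eliminated.
    """
    img = _check_uint8(img)
    thr = p.label_threshold
    if thr is None:
        thr = filters.threshold_otsu(img)
    binary = img > thr
    selem = morphology.disk(p.morph_radius)
    opened = morphology.opening(binary, selem)
    labels, n = ndimage.label(opened)
    if n == 0:
        raise NoBreastRegionError("no breast region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    breast_mask = labels == (1 + int(np.argmax(sizes)))
    breast_mask = ndimage.binary_fill_holes(breast_mask)
    out = np.where(breast_mask, img, 0).astype(np.uint8)
    return out, breast_mask


def median_filter(img: GrayImage, kernel: int = 3) -> GrayImage:
    """Median of each ``kernel``x``kernel`` neighbourhood (reflected edges)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd, got {kernel}")
    return ndimage.median_filter(_check_uint8(img), size=kernel, mode="reflect")


def clahe(img: GrayImage, clip: float = 0.01, tiles: tuple[int, int] = (8, 8)) -> GrayImage:
    """Contrast-limited adaptive histogram equalisation.

    ``clip`` is the relative clip limit; ``tiles`` the (rows, cols) grid of
    local histograms, interpolated bilinearly between tiles.
    """
    img = _check_uint8(img)
    th, tw = tiles
    if th > img.shape[0] or tw > img.shape[1]:
        raise ValueError(f"tile grid {tiles} larger than image {img.shape}")
    if img.min() == img.max():
        return img.copy()  # no contrast to create
    kernel_size = (max(1, img.shape[0] // th), max(1, img.shape[1] // tw))
    out = exposure.equalize_adapthist(img, kernel_size=kernel_size, clip_limit=clip)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def unsharp_mask(img: GrayImage, radius: float = 2.0, amount: float = 1.0) -> GrayImage:
    """out = clip(img + amount * (img - gaussian_blur(img, radius)), 0, 255)."""
    if radius <= 0:
        raise ValueError("usm radius must be > 0")
    if amount < 0:
        raise ValueError("usm amount must be >= 0")
    img = _check_uint8(img)
    if amount == 0:
        return img.copy()
    f = img.astype(np.float64)
    blurred = ndimage.gaussian_filter(f, sigma=radius, mode="reflect")
    out = f + amount * (f - blurred)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_combo(img: GrayImage, combo: str, p: FilterParams = FilterParams()) -> GrayImage:
    """Apply one of the five combinations, operators in name order."""
    key = combo.upper().replace("&", "_").replace("-", "_")
    if key not in COMBOS:
        raise ValueError(f"unknown combo {combo!r}: expected one of {sorted(COMBOS)}")
    out = _check_uint8(img)
    for step in COMBOS[key]:
        if step == "mf":
            out = median_filter(out, p.median_kernel)
        elif step == "clahe":
            out = clahe(out, p.clahe_clip, p.clahe_tiles)
        else:
            out = unsharp_mask(out, p.usm_radius, p.usm_amount)
    return out
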