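"""Synthetic phantom mammograms with pixel-level ground truth.

Each phantom emulates an MLO-view screening mammogram: a near-black
background carrying a bright acquisition label, a half-elliptical breast
attached to the chest-wall edge with smooth low-frequency tissue texture,
a brighter pectoral-muscle wedge in the upper chest-wall corner, and an
optional lesion — benign lesions are smooth high-intensity discs, malignant
ones spiculated blobs with jagged boundaries. Gaussian and salt-and-pepper
noise are configurable. Every phantom comes with mutually exclusive
background / pectoral / breast truth masks (the lesion mask is nested in
the breast) so segmentation and ROI stages can be scored exactly.

Benign/malign separability is carried by shape and boundary roughness as
well as intensity: the lesion contrast and spicule count are the difficulty
dials of the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .mias_io import GrayImage, MammogramRecord, write_metadata, write_pgm

__all__ = ["PhantomParams", "generate_phantom", "generate_cohort", "save_cohort"]

# nominal intensities of the compartments (8-bit scale)
_BG_LEVEL = 5
_BREAST_LEVEL = 115
_PECTORAL_OFFSET = 50
_LABEL_LEVEL = 250


@dataclass
class PhantomParams:
    """Generator knobs; identical params (same seed) give bit-identical output."""

    seed: int = 0
    size: int = 1024
    laterality: str = "left"
    lesion: str = "none"  # none | benign | malign
    lesion_center: Optional[tuple[int, int]] = None  # (x, y); default mid-breast
    lesion_radius: Optional[int] = None  # default 6% of side
    lesion_contrast: int = 90
    n_spicules: int = 9
    pectoral_fraction: float = 0.35  # wedge width at the top edge, as fraction of side
    label_box: Optional[tuple[int, int, int, int]] = None  # (x0, y0, x1, y1)
    noise_gaussian_sd: float = 2.0
    noise_salt_pepper_p: float = 0.0

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be left|right, got {self.laterality!r}")
        if self.lesion not in ("none", "benign", "malign"):
            raise ValueError(f"lesion must be none|benign|malign, got {self.lesion!r}")
        if not 0.0 <= self.noise_salt_pepper_p <= 1.0:
            raise ValueError("noise_salt_pepper_p must lie in [0, 1]")
        if not 0.0 <= self.pectoral_fraction <= 0.5:
            raise ValueError("pectoral_fraction must lie in [0, 0.5]")


def _smooth_noise(rng: np.random.Generator, size: int, coarse: int, amplitude: float) -> np.ndarray:
    """Low-frequency texture: a coarse random grid upsampled with cubic splines."""
    grid = rng.standard_normal((coarse, coarse))
    return ndimage.zoom(grid, size / coarse, order=3, mode="reflect")[:size, :size] * amplitude


def _breast_mask(size: int) -> np.ndarray:
    """Half-ellipse attached to the left edge (chest wall at x = 0)."""
    y, x = np.mgrid[0:size, 0:size]
    a, b, cy = 0.55 * size, 0.45 * size, 0.55 * size
    return (x / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _pectoral_mask(size: int, fraction: float) -> np.ndarray:
    """Wedge from the top-left corner, width ``fraction*size`` at y = 0,
    tapering to zero at y = size/2."""
    if fraction <= 0:
        return np.zeros((size, size), dtype=bool)
    y, x = np.mgrid[0:size, 0:size]
    depth = 0.5 * size
    return (y < depth) & (x < fraction * size * (1.0 - y / depth))


def _lesion(rng, size, center, radius, kind, n_spicules):
    """Return (intensity profile in [0,1], truth mask) for a lesion."""
    cx, cy = center
    y, x = np.mgrid[0:size, 0:size]
    r = np.hypot(x - cx, y - cy)
    if kind == "benign":
        mask = r <= radius
        profile = np.clip(1.0 - (r / radius) ** 2, 0.0, None) ** 1.5
    else:
        theta = np.arctan2(y - cy, x - cx)
        phase = rng.uniform(0, 2 * np.pi)
        # narrow radial spikes riding on a smaller core disc
        spikes = np.abs(np.cos(0.5 * n_spicules * theta + phase)) ** 10
        jag = 0.10 * np.cos(3 * n_spicules * theta + 2.0 * phase)
        r_edge = radius * (0.55 + 0.45 * spikes + jag)
        mask = r <= r_edge
        profile = np.where(mask, np.clip(1.0 - (r / r_edge) ** 2, 0.0, None) ** 0.7, 0.0)
    return profile, mask


def generate_phantom(params: PhantomParams) -> tuple[MammogramRecord, dict[str, np.ndarray]]:
    """Render one phantom.

    Returns the record (with pixel data attached) and the truth masks
    ``{"background", "pectoral", "breast", "lesion"}``; the first three
    partition the frame and the lesion mask is a subset of the breast mask.
    Raises ``ValueError`` when the requested lesion does not fit inside the
    breast region.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    s = p.size
    # compose on the left-laterality canvas, mirror at the end if needed
    breast_full = _breast_mask(s)
    pectoral = _pectoral_mask(s, p.pectoral_fraction)  # wedge reaches the corner
    breast = breast_full & ~pectoral

    img = np.full((s, s), float(_BG_LEVEL))
    img += _smooth_noise(rng, s, 6, 1.0)

    tissue = _BREAST_LEVEL + _smooth_noise(rng, s, 8, 12.0)
    # gentle falloff toward the skin line
    y, x = np.mgrid[0:s, 0:s]
    a, b, cy = 0.55 * s, 0.45 * s, 0.55 * s
    rho = np.sqrt((x / a) ** 2 + ((y - cy) / b) ** 2)
    tissue -= 25.0 * np.clip(rho - 0.7, 0.0, None) / 0.3
    img[breast] = tissue[breast]

    pect_level = _BREAST_LEVEL + _PECTORAL_OFFSET + _smooth_noise(rng, s, 6, 5.0)
    pect_level -= 10.0 * (y / s)  # slightly darker toward the wedge tip
    img[pectoral] = pect_level[pectoral]

    lesion_mask = np.zeros((s, s), dtype=bool)
    center = p.lesion_center
    radius = p.lesion_radius
    if p.lesion != "none":
        if center is None:
            center = (int(0.32 * s), int(0.55 * s))
        if radius is None:
            radius = max(4, int(0.06 * s))
        # dedicated stream: lesion draws must not shift the main noise stream
        lesion_rng = np.random.default_rng([p.seed, 104729])
        profile, lesion_mask = _lesion(lesion_rng, s, center, radius, p.lesion, p.n_spicules)
        if not lesion_mask.any():
            raise ValueError("lesion mask is empty")
        if (lesion_mask & ~breast).any():
            raise ValueError("lesion lies (partly) outside the breast region")
        img += p.lesion_contrast * profile

    box = p.label_box
    if box is None:
        box = (int(0.78 * s), int(0.05 * s), int(0.92 * s), int(0.11 * s))
    x0, y0, x1, y1 = box
    label = np.zeros((s, s), dtype=bool)
    label[y0:y1, x0:x1] = True
    if (label & (breast_full | pectoral)).any():
        raise ValueError("label box overlaps the breast region")
    img[label] = _LABEL_LEVEL + _smooth_noise(rng, s, 4, 2.0)[label]

    if p.noise_gaussian_sd > 0:
        img += rng.normal(0.0, p.noise_gaussian_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if p.noise_salt_pepper_p > 0:
        u = rng.random(img.shape)
        img[u < p.noise_salt_pepper_p / 2] = 0
        img[(u >= p.noise_salt_pepper_p / 2) & (u < p.noise_salt_pepper_p)] = 255

    background = ~(breast | pectoral)
    if p.laterality == "right":
        img = np.fliplr(img)
        background = np.fliplr(background)
        pectoral = np.fliplr(pectoral)
        breast = np.fliplr(breast)
        lesion_mask = np.fliplr(lesion_mask)
        if center is not None:
            center = (s - 1 - center[0], center[1])

    record = MammogramRecord(
        id=f"syn{p.seed:05d}",
        laterality=p.laterality,
        tissue_class="normal" if p.lesion == "none" else "abnormal",
        severity=None if p.lesion == "none" else p.lesion,
        lesion_center=center if p.lesion != "none" else None,
        lesion_radius=radius if p.lesion != "none" else None,
        image=img,
    )
    masks = {
        "background": background,
        "pectoral": pectoral,
        "breast": breast,
        "lesion": lesion_mask,
    }
    return record, masks


def generate_cohort(
    n_normal: int,
    n_benign: int,
    n_malign: int,
    seed: int = 0,
    size: int = 1024,
    contrast_range: tuple[int, int] = (60, 100),
    noise_gaussian_sd: float = 2.0,
    noise_salt_pepper_p: float = 0.0,
) -> list[tuple[MammogramRecord, dict[str, np.ndarray]]]:
    """Reproducible cohort with randomised laterality and lesion geometry.

    Lesion centres are drawn from a zone guaranteed to lie inside the breast
    and clear of the pectoral wedge; radii span 4-8% of the image side and
    contrasts are uniform over ``contrast_range``.
    """
    if min(n_normal, n_benign, n_malign) < 0:
        raise ValueError("cohort counts must be non-negative")
    master = np.random.default_rng(seed)
    out = []
    kinds = ["none"] * n_normal + ["benign"] * n_benign + ["malign"] * n_malign
    for idx, kind in enumerate(kinds):
        sub = np.random.default_rng(master.integers(0, 2**31 - 1))
        lat = "left" if sub.random() < 0.5 else "right"
        params = PhantomParams(
            seed=int(sub.integers(0, 2**31 - 1)),
            size=size,
            laterality=lat,
            lesion=kind,
            noise_gaussian_sd=noise_gaussian_sd,
            noise_salt_pepper_p=noise_salt_pepper_p,
        )
        if kind != "none":
            radius = int(sub.uniform(0.04, 0.08) * size)
            # sampled on the left-canvas; generate_phantom mirrors for right
            cx = int(sub.uniform(0.24, 0.40) * size)
            cy_ = int(sub.uniform(0.45, 0.68) * size)
            params = replace(
                params,
                lesion_center=(cx, cy_),
                lesion_radius=radius,
                lesion_contrast=int(sub.uniform(*contrast_range)),
            )
        record, masks = generate_phantom(params)
        record.id = f"syn{idx:04d}"
        out.append((record, masks))
    return out


def save_cohort(cohort, out_dir, write_masks: bool = True) -> None:
    """Write PGMs, a mini-MIAS-dialect metadata table and 0/255 truth masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for record, masks in cohort:
        write_pgm(record.image, out / f"{record.id}.pgm")
        if write_masks:
            for name, m in masks.items():
                write_pgm((m.astype(np.uint8)) * 255, out / f"{record.id}_{name}.pgm")
        records.append(record)
    size = cohort[0][0].image.shape[0] if cohort else 1024
    write_metadata(records, out / "info.txt", image_height=size)
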