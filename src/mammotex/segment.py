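"""Intensity k-means segmentation, pectoral-muscle removal, ROI extraction.

A mammogram partitions naturally into three intensity clusters —
background, breast tissue and the brighter pectoral muscle — so the
clustering objective

    J = sum_j sum_i || x_i^(j) - c_j ||^2

is minimised over scalar pixel intensities with Lloyd's algorithm.
Initial centroids sit at evenly spaced quantiles of the intensity
distribution (deterministic, avoids empty clusters); additional starts —
the centroids of the optimal contiguous 1-D partition found by a small
dynamic programme, plus two seeded jittered quantile starts — guard
against 1-D local optima, and the best-J Lloyd fixed point is kept. Assignment ties go to the lower cluster index; an emptied
cluster is re-seeded at the point farthest from its centroid.

The pectoral muscle is identified as the cluster whose connected component
touches the top corner on the chest-wall side and removed before texture
analysis. ROIs are square patches: lesion-centred for abnormal cases, and
for normal cases centred on the densest (brightest-cluster) breast region,
nudged inward so the patch stays inside the breast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .mias_io import GrayImage, MammogramRecord

log = logging.getLogger(__name__)

__all__ = [
    "KMeansModel",
    "ROI",
    "MissingGeometryError",
    "kmeans_segment",
    "remove_pectoral",
    "extract_roi",
]


class MissingGeometryError(ValueError):
    """Abnormal case without lesion coordinates cannot be ROI-centred."""


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray  # shape (k,), sorted ascending
    assignments: np.ndarray  # int array, image shape
    J: float  # final within-cluster sum of squares
    J_history: list[float] = field(default_factory=list)
    n_iter: int = 0


@dataclass
class ROI:
    source_id: str
    patch: GrayImage
    mask: np.ndarray  # bool, in-ROI (breast) pixels, same shape as patch
    provenance: str  # "lesion-centered" | "cluster-derived"
    tissue_class: str  # normal | abnormal
    severity: Optional[str] = None  # benign | malign | None
    center: tuple[int, int] = (0, 0)  # (x, y) in the source image


def _dp_centroids(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Centroids of the optimal contiguous partition of sorted 1-D values
    (dynamic programme over prefix sums); optimal 1-D clusters are intervals,
    so this is the global k-means optimum and a Lloyd fixed point."""
    n = len(values)
    w = np.r_[0.0, np.cumsum(weights)]
    wx = np.r_[0.0, np.cumsum(weights * values)]
    wx2 = np.r_[0.0, np.cumsum(weights * values**2)]

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=np.intp)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for b in range(j, n + 1):
            a = np.arange(j - 1, b)
            ws = w[b] - w[a]
            s = wx[b] - wx[a]
            seg = np.where(ws > 0, wx2[b] - wx2[a] - s * s / np.maximum(ws, 1e-300), 0.0)
            c = cost[j - 1, a] + seg
            i = int(np.argmin(c))
            cost[j, b] = c[i]
            back[j, b] = a[i]
    cuts = [n]
    for j in range(k, 0, -1):
        cuts.append(int(back[j, cuts[-1]]))
    cuts = cuts[::-1]
    cents = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        ws = w[b] - w[a]
        cents.append((wx[b] - wx[a]) / ws if ws > 0 else values[min(a, n - 1)])
    return np.array(cents)


def _lloyd(values: np.ndarray, weights: np.ndarray, centroids: np.ndarray,
           tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, list[float], int]:
    """Weighted 1-D Lloyd iterations over the distinct intensity values."""
    k = len(centroids)
    history: list[float] = []
    assign = np.zeros(len(values), dtype=np.intp)
    for it in range(1, max_iter + 1):
        d2 = (values[:, None] - centroids[None, :]) ** 2
        assign = np.argmin(d2, axis=1)  # argmin takes the lower index on ties
        J = float(np.sum(weights * d2[np.arange(len(values)), assign]))
        history.append(J)
        new = centroids.copy()
        for j in range(k):
            sel = assign == j
            wj = weights[sel].sum()
            if wj > 0:
                new[j] = np.sum(weights[sel] * values[sel]) / wj
            else:  # re-seed an emptied cluster at the farthest point
                far = int(np.argmax(d2[np.arange(len(values)), assign]))
                new[j] = values[far]
        if np.max(np.abs(new - centroids)) < tol:
            centroids = new
            break
        centroids = new
    d2 = (values[:, None] - centroids[None, :]) ** 2
    assign = np.argmin(d2, axis=1)
    J = float(np.sum(weights * d2[np.arange(len(values)), assign]))
    history.append(J)
    return centroids, assign, J, history, it


def kmeans_segment(
    img: GrayImage,
    breast_mask: Optional[np.ndarray] = None,
    k: int = 3,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> KMeansModel:
    """Cluster pixel intensities into ``k`` groups with Lloyd's algorithm.

    Centroids are fitted on the pixels inside ``breast_mask`` (all pixels
    when it is None); every pixel of the frame is then assigned to its
    nearest centroid, so with a masked, zeroed background the out-of-mask
    pixels land in the darkest (background) cluster by construction. If
    fewer than ``k`` distinct intensities exist, ``k`` is reduced with a
    warning. The objective J is reported over the fitted pixels and is
    non-increasing across iterations.
    """
    img = np.asarray(img)
    if k < 1:
        raise ValueError("k must be >= 1")
    considered = img[breast_mask] if breast_mask is not None else img.ravel()
    if considered.size == 0:
        raise ValueError("no pixels to cluster")
    values, counts = np.unique(considered, return_counts=True)
    values = values.astype(np.float64)
    weights = counts.astype(np.float64)
    if len(values) < k:
        warnings.warn(f"only {len(values)} distinct intensities; reducing k from {k}")
        k = len(values)

    # quantile init + two seeded jittered restarts; keep the best J
    rng = np.random.default_rng(seed)
    q = (np.arange(k) + 0.5) / k
    base = np.quantile(np.repeat(values, counts.astype(np.intp)), q) if k > 1 else np.array(
        [np.average(values, weights=weights)]
    )
    inits = [base, _dp_centroids(values, weights, k)]
    span = values.max() - values.min()
    for _ in range(2):
        jitter = rng.uniform(-0.15, 0.15, size=k) * max(span, 1.0)
        inits.append(np.sort(np.clip(base + jitter, values.min(), values.max())))
    best = None
    for init in inits:
        res = _lloyd(values, weights, init.astype(np.float64), tol, max_iter)
        if best is None or res[2] < best[2]:
            best = res
    centroids, assign_vals, J, history, n_iter = best

    # sort clusters by centroid so index order is dark -> bright
    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    remap = np.empty(k, dtype=np.intp)
    remap[order] = np.arange(k)
    assign_vals = remap[assign_vals]

    # full-frame assignment to the nearest centroid (ties -> lower index)
    lut_vals = np.arange(256, dtype=np.float64)
    lut = np.argmin(np.abs(lut_vals[:, None] - centroids[None, :]), axis=1)
    assignments = lut[img]
    return KMeansModel(k=k, centroids=centroids, assignments=assignments,
                       J=J, J_history=history, n_iter=n_iter)


def remove_pectoral(
    model: KMeansModel, img: GrayImage, laterality: str
) -> tuple[GrayImage, np.ndarray]:
    """Zero the pectoral muscle: the non-background cluster whose connected
    component touches the top corner on the chest-wall side.

    Returns (cleaned image, pectoral mask). If no non-background cluster
    reaches that corner, nothing is removed (with a warning).
    """
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be left|right")
    img = np.asarray(img)
    h, w = img.shape
    win = max(3, h // 100)
    cols = slice(0, win) if laterality == "left" else slice(w - win, w)
    corner = model.assignments[0:win, cols]
    bg = int(np.argmin(model.centroids))
    cand = corner[corner != bg]
    if cand.size == 0:
        warnings.warn("no non-background cluster touches the chest-wall corner; "
                      "nothing removed")
        return img.copy(), np.zeros_like(img, dtype=bool)
    c = int(np.bincount(cand).argmax())
    cluster_mask = model.assignments == c
    labels, _ = ndimage.label(cluster_mask)
    corner_labels = labels[0:win, cols]
    ids = np.unique(corner_labels[corner_labels > 0])
    pect = np.isin(labels, ids)
    cleaned = np.where(pect, 0, img).astype(img.dtype)
    return cleaned, pect


def extract_roi(
    record: MammogramRecord,
    cleaned: GrayImage,
    model: KMeansModel,
    patch_size: int = 128,
    breast_mask: Optional[np.ndarray] = None,
) -> ROI:
    """Cut the square analysis patch for one case.

    Abnormal cases are centred on the recorded lesion position (clipped at
    the frame border). Normal cases take the centroid of the brightest
    non-background cluster within the breast, shifted minimally inward so
    the whole patch fits inside breast tissue. ``breast_mask`` defaults to
    the non-zero pixels of ``cleaned`` (background and pectoral are zeroed
    upstream).
    """
    cleaned = np.asarray(cleaned)
    h, w = cleaned.shape
    if breast_mask is None:
        breast_mask = cleaned > 0
    if record.tissue_class == "abnormal":
        if record.lesion_center is None:
            raise MissingGeometryError(f"{record.id}: abnormal case without lesion geometry")
        cx, cy = record.lesion_center
        provenance = "lesion-centered"
    else:
        bright = int(np.argmax(model.centroids))
        region = (model.assignments == bright) & breast_mask
        if not region.any():
            region = breast_mask
        if not region.any():
            raise ValueError(f"{record.id}: empty breast mask")
        ys, xs = np.nonzero(region)
        cx, cy = float(xs.mean()), float(ys.mean())
        # nudge the centre to the nearest point deep enough inside the breast
        dist = ndimage.distance_transform_edt(breast_mask)
        need = (patch_size / 2.0) * np.sqrt(2.0)
        if dist[int(round(cy)), int(round(cx))] < need:
            deep = dist >= need
            if deep.any():
                dy, dx = np.nonzero(deep)
                i = int(np.argmin((dx - cx) ** 2 + (dy - cy) ** 2))
                cx, cy = float(dx[i]), float(dy[i])
            else:
                iy, ix = np.unravel_index(int(np.argmax(dist)), dist.shape)
                cx, cy = float(ix), float(iy)
        cx, cy = int(round(cx)), int(round(cy))
        provenance = "cluster-derived"

    half = patch_size // 2
    r0 = int(np.clip(cy - half, 0, max(0, h - patch_size)))
    c0 = int(np.clip(cx - half, 0, max(0, w - patch_size)))
    r1, c1 = min(h, r0 + patch_size), min(w, c0 + patch_size)
    patch = cleaned[r0:r1, c0:c1]
    mask = breast_mask[r0:r1, c0:c1]
    if not mask.any():
        mask = np.ones_like(patch, dtype=bool)
        log.warning("%s: patch holds no breast pixels; using full patch", record.id)
    return ROI(
        source_id=record.id,
        patch=patch,
        mask=mask,
        provenance=provenance,
        tissue_class=record.tissue_class,
        severity=record.severity,
        center=(int(cx), int(cy)),
    )
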