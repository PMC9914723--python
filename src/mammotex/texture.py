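"""Gray-level co-occurrence and run-length texture features.

Each ROI yields 33 features: 22 from the gray-level co-occurrence matrix
(GLCM, the extended Haralick set) and 11 from the gray-level run-length
matrix (GLRLM, the Galloway/Chu set). Both matrices are built at the four
standard angles 0°, 45°, 90° and 135° and every feature is reported as
the arithmetic mean over the four angles.

Conventions (all configurable where meaningful, all recorded in reports):

* intensities are quantized range-relatively into ``Ng`` uniform bins
  (default 8) inside the ROI mask; out-of-mask pixels carry a sentinel and
  never contribute pairs or runs;
* GLCM accumulation is symmetric (each ordered pair counted both ways);
* gray levels and run lengths are indexed from 1 wherever they enter a
  feature weight, so low-gray-level emphases stay finite;
* logarithms are base 2 with the 0·log 0 = 0 convention; the information
  measures guard their denominators with max(HX, HY) and eps = 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mias_io import GrayImage
from .segment import ROI

__all__ = [
    "ANGLES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "FEATURE_NAMES",
    "GLCMatrix",
    "RunLengthMatrix",
    "DegenerateROIError",
    "quantize",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "roi_features",
]

ANGLES = (0, 45, 90, 135)
_EPS = 1e-12

#: canonical feature order: the 22 GLCM names then the 11 GLRLM names
GLCM_FEATURE_NAMES = [
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation_m",
    "glcm_correlation_p",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity_m",
    "glcm_homogeneity_p",
    "glcm_max_probability",
    "glcm_sum_of_squares",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment_normalized",
]
GLRLM_FEATURE_NAMES = [
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
]
FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES

# row/col offsets of the four angles, skimage convention (0° = east)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegenerateROIError(ValueError):
    """ROI too small to form any co-occurring pixel pair."""


@dataclass
class GLCMatrix:
    counts: np.ndarray  # (Ng, Ng) symmetric co-occurrence counts
    Ng: int
    d: int
    theta: int

    @property
    def p(self) -> np.ndarray:
        """Normalized co-occurrence probabilities (sums to 1)."""
        total = self.counts.sum()
        return self.counts / total


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # (Ng, Nl): runs of level i (row) and length j (col, 1-based)
    Ng: int
    theta: int
    Np: int  # in-mask pixels considered

    @property
    def Nr(self) -> int:
        return int(self.counts.sum())


def quantize(patch: GrayImage, mask: np.ndarray | None, levels: int = 8) -> np.ndarray:
    """Range-relative uniform quantization into ``levels`` bins.

    The in-mask [min, max] range maps onto levels 0..levels-1; a constant
    patch occupies level 0 only. Out-of-mask pixels become the sentinel -1.
    Because binning is range-relative, adding a constant to every pixel
    leaves the result unchanged.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    patch = np.asarray(patch)
    if mask is None:
        mask = np.ones_like(patch, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = patch[mask].astype(np.float64)
    lo, hi = vals.min(), vals.max()
    q = np.full(patch.shape, -1, dtype=np.int64)
    if hi == lo:
        q[mask] = 0
    else:
        scaled = (patch.astype(np.float64) - lo) / (hi - lo) * levels
        q[mask] = np.clip(scaled[mask].astype(np.int64), 0, levels - 1)
    return q


def glcm(quantized: np.ndarray, d: int = 1, theta: int = 0, levels: int | None = None) -> GLCMatrix:
    """Symmetric co-occurrence counts for displacement (d, theta).

    Only pairs with both pixels in-mask (level >= 0) are counted; each
    ordered pair is accumulated in both (i, j) and (j, i).
    """
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ANGLES}, got {theta}")
    if d < 1:
        raise ValueError("d must be >= 1")
    q = np.asarray(quantized)
    Ng = int(levels if levels is not None else q.max() + 1)
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a >= 0) & (b >= 0)
    ai, bi = a[valid], b[valid]
    if ai.size == 0:
        raise DegenerateROIError("degenerate ROI: no co-occurring pixel pair")
    counts = np.zeros((Ng, Ng), dtype=np.float64)
    np.add.at(counts, (ai, bi), 1.0)
    np.add.at(counts, (bi, ai), 1.0)
    return GLCMatrix(counts=counts, Ng=Ng, d=d, theta=theta)


def _entropy2(p: np.ndarray) -> float:
    """-sum p log2 p with 0 log 0 = 0."""
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(M: GLCMatrix) -> dict[str, float]:
    """The 22 extended-Haralick features of one co-occurrence matrix.

    Index weights are 1-based (i, j in 1..Ng). Correlation-type features
    are defined as 0 when a marginal is degenerate (sigma = 0).
    """
    p = M.p
    Ng = M.Ng
    I = np.arange(1, Ng + 1, dtype=np.float64)
    ii = I[:, None] * np.ones((1, Ng))
    jj = ii.T
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(I * px))
    mu_y = float(np.sum(I * py))
    sd_x = math.sqrt(max(float(np.sum((I - mu_x) ** 2 * px)), 0.0))
    sd_y = math.sqrt(max(float(np.sum((I - mu_y) ** 2 * py)), 0.0))

    # sum (k = i+j in 2..2Ng) and difference (k = |i-j| in 0..Ng-1) distributions
    p_sum = np.zeros(2 * Ng + 1)
    np.add.at(p_sum, (ii + jj).astype(np.intp), p)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.intp), p)
    k_sum = np.arange(2 * Ng + 1, dtype=np.float64)
    k_diff = np.arange(Ng, dtype=np.float64)

    HX = _entropy2(px)
    HY = _entropy2(py)
    HXY = _entropy2(p)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    HXY1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    HXY2 = _entropy2(pxpy)

    f: dict[str, float] = {}
    f["glcm_autocorrelation"] = float(np.sum(ii * jj * p))
    f["glcm_contrast"] = float(np.sum((ii - jj) ** 2 * p))
    if sd_x > _EPS and sd_y > _EPS:
        corr_m = float(np.sum((ii - mu_x) * (jj - mu_y) * p)) / (sd_x * sd_y)
        corr_p = (float(np.sum(ii * jj * p)) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr_m = corr_p = 0.0
    f["glcm_correlation_m"] = corr_m
    f["glcm_correlation_p"] = corr_p
    f["glcm_cluster_prominence"] = float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p))
    f["glcm_cluster_shade"] = float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p))
    f["glcm_dissimilarity"] = float(np.sum(np.abs(ii - jj) * p))
    f["glcm_energy"] = float(np.sum(p**2))
    f["glcm_entropy"] = HXY
    f["glcm_homogeneity_m"] = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    f["glcm_homogeneity_p"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    f["glcm_max_probability"] = float(p.max())
    f["glcm_sum_of_squares"] = float(np.sum((ii - mu_x) ** 2 * p))
    sum_avg = float(np.sum(k_sum * p_sum))
    f["glcm_sum_average"] = sum_avg
    f["glcm_sum_variance"] = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    f["glcm_sum_entropy"] = _entropy2(p_sum)
    diff_avg = float(np.sum(k_diff * p_diff))
    f["glcm_difference_variance"] = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    f["glcm_difference_entropy"] = _entropy2(p_diff)
    denom = max(HX, HY)
    f["glcm_imc1"] = (HXY - HXY1) / denom if denom > _EPS else 0.0
    f["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))
    f["glcm_inverse_difference_normalized"] = float(
        np.sum(p / (1.0 + np.abs(ii - jj) / Ng))
    )
    f["glcm_inverse_difference_moment_normalized"] = float(
        np.sum(p / (1.0 + (ii - jj) ** 2 / Ng**2))
    )
    return f


def _lines(q: np.ndarray, theta: int) -> list[np.ndarray]:
    """The scan lines of the grid along direction theta."""
    h, w = q.shape
    if theta == 0:
        return [q[r] for r in range(h)]
    if theta == 90:
        return [q[:, c] for c in range(w)]
    if theta == 135:  # offset (-1,-1): lines are main diagonals
        return [np.diagonal(q, offset=o) for o in range(-(h - 1), w)]
    # theta == 45, offset (-1, 1): anti-diagonals
    fl = np.fliplr(q)
    return [np.diagonal(fl, offset=o) for o in range(-(h - 1), w)]


def glrlm(quantized: np.ndarray, theta: int = 0, levels: int | None = None) -> RunLengthMatrix:
    """Run-length counts along direction theta.

    A run is a maximal collinear segment of equal in-mask levels;
    out-of-mask (sentinel) pixels break runs and are not counted.
    """
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ANGLES}, got {theta}")
    q = np.asarray(quantized)
    if not (q >= 0).any():
        raise ValueError("empty mask")
    Ng = int(levels if levels is not None else q.max() + 1)
    Nl = max(q.shape)
    counts = np.zeros((Ng, Nl), dtype=np.float64)
    Np = 0
    for line in _lines(q, theta):
        n = len(line)
        if n == 0:
            continue
        # boundaries where the level changes (sentinel counts as a change)
        idx = np.flatnonzero(np.r_[True, line[1:] != line[:-1], True])
        for s, e in zip(idx[:-1], idx[1:]):
            lvl = line[s]
            if lvl >= 0:
                counts[lvl, e - s - 1] += 1.0
                Np += e - s
    return RunLengthMatrix(counts=counts, Ng=Ng, theta=theta, Np=Np)


def glrlm_features(R: RunLengthMatrix) -> dict[str, float]:
    """The 11 Galloway/Chu run-length features, normalized by the run count.

    Gray levels i and run lengths j are 1-based in every weight; the run
    percentage RP divides the run count by the pixels considered.
    """
    Nr = R.Nr
    if Nr == 0:
        raise ValueError("run-length matrix holds no runs")
    r = R.counts
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    f = {
        "glrlm_sre": float(np.sum(r / j**2)) / Nr,
        "glrlm_lre": float(np.sum(r * j**2)) / Nr,
        "glrlm_gln": float(np.sum(r.sum(axis=1) ** 2)) / Nr,
        "glrlm_rln": float(np.sum(r.sum(axis=0) ** 2)) / Nr,
        "glrlm_rp": Nr / R.Np,
        "glrlm_lgre": float(np.sum(r / i**2)) / Nr,
        "glrlm_hgre": float(np.sum(r * i**2)) / Nr,
        "glrlm_srlge": float(np.sum(r / (i**2 * j**2))) / Nr,
        "glrlm_srhge": float(np.sum(r * i**2 / j**2)) / Nr,
        "glrlm_lrlge": float(np.sum(r * j**2 / i**2)) / Nr,
        "glrlm_lrhge": float(np.sum(r * i**2 * j**2)) / Nr,
    }
    return f


def roi_features(roi: ROI, d: int = 1, levels: int = 8) -> dict[str, float]:
    """All 33 features of one ROI, averaged over the four angles."""
    q = quantize(roi.patch, roi.mask, levels)
    acc = {name: 0.0 for name in FEATURE_NAMES}
    for theta in ANGLES:
        fg = glcm_features(glcm(q, d=d, theta=theta, levels=levels))
        fr = glrlm_features(glrlm(q, theta=theta, levels=levels))
        for name, v in {**fg, **fr}.items():
            acc[name] += v
    out = {name: acc[name] / len(ANGLES) for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature(s): {bad}")
    return out
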