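"""Independent brute-force oracles: naive pair/run enumeration, direct
feature formulas, exhaustive Mann-Whitney pair counting, and exhaustive
1-D k-means partitioning. Deliberately loop-based and separate from the
package's vectorized implementations."""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_brute(q, d, theta, levels):
    """Symmetric co-occurrence counts by explicit pixel-pair enumeration."""
    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    return P


def _log2(x):
    return math.log2(x) if x > 0 else 0.0


def glcm_features_brute(P):
    """The 22 features evaluated by direct looping over the matrix."""
    Ng = P.shape[0]
    total = P.sum()
    p = P / total
    px = [sum(p[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(p[i][j] for i in range(Ng)) for j in range(Ng)]
    mu_x = sum((i + 1) * px[i] for i in range(Ng))
    mu_y = sum((j + 1) * py[j] for j in range(Ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(Ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(Ng)))
    p_sum = [0.0] * (2 * Ng + 1)
    p_diff = [0.0] * Ng
    for i in range(Ng):
        for j in range(Ng):
            p_sum[(i + 1) + (j + 1)] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    HX = -sum(v * _log2(v) for v in px)
    HY = -sum(v * _log2(v) for v in py)
    HXY = -sum(p[i][j] * _log2(p[i][j]) for i in range(Ng) for j in range(Ng))
    HXY1 = -sum(
        p[i][j] * _log2(px[i] * py[j]) for i in range(Ng) for j in range(Ng) if p[i][j] > 0
    )
    HXY2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j]) for i in range(Ng) for j in range(Ng)
    )
    f = {}
    f["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    f["glcm_contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng))
    if sd_x > 1e-12 and sd_y > 1e-12:
        corr = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * p[i][j] for i in range(Ng) for j in range(Ng)
        ) / (sd_x * sd_y)
        corr_p = (f["glcm_autocorrelation"] - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr = corr_p = 0.0
    f["glcm_correlation_m"] = corr
    f["glcm_correlation_p"] = corr_p
    f["glcm_cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    f["glcm_cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    f["glcm_dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    f["glcm_energy"] = sum(p[i][j] ** 2 for i in range(Ng) for j in range(Ng))
    f["glcm_entropy"] = HXY
    f["glcm_homogeneity_m"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng)
    )
    f["glcm_homogeneity_p"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng)
    )
    f["glcm_max_probability"] = max(p[i][j] for i in range(Ng) for j in range(Ng))
    f["glcm_sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    sa = sum(k * p_sum[k] for k in range(len(p_sum)))
    f["glcm_sum_average"] = sa
    f["glcm_sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(len(p_sum)))
    f["glcm_sum_entropy"] = -sum(v * _log2(v) for v in p_sum)
    da = sum(k * p_diff[k] for k in range(Ng))
    f["glcm_difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(Ng))
    f["glcm_difference_entropy"] = -sum(v * _log2(v) for v in p_diff)
    denom = max(HX, HY)
    f["glcm_imc1"] = (HXY - HXY1) / denom if denom > 1e-12 else 0.0
    f["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))
    f["glcm_inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / Ng) for i in range(Ng) for j in range(Ng)
    )
    f["glcm_inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / Ng**2) for i in range(Ng) for j in range(Ng)
    )
    return f


def _scan_lines(q, theta):
    h, w = q.shape
    if theta == 0:
        return [list(q[r]) for r in range(h)]
    if theta == 90:
        return [list(q[:, c]) for c in range(w)]
    lines = []
    if theta == 135:
        starts = [(r, 0) for r in range(h)] + [(0, c) for c in range(1, w)]
        step = (1, 1)
    else:  # 45: down-left to up-right direction
        starts = [(r, 0) for r in range(h)] + [(h - 1, c) for c in range(1, w)]
        step = (-1, 1)
    for r0, c0 in starts:
        line, r, c = [], r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(q[r, c])
            r, c = r + step[0], c + step[1]
        lines.append(line)
    return lines


def glrlm_counts_brute(q, theta, levels):
    """Run-length counts by explicit per-line scanning."""
    Nl = max(q.shape)
    R = np.zeros((levels, Nl))
    Np = 0
    for line in _scan_lines(q, theta):
        i = 0
        while i < len(line):
            if line[i] < 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            R[line[i], j - i - 1] += 1
            Np += j - i
            i = j
    return R, Np


def glrlm_features_brute(R, Np):
    Ng, Nl = R.shape
    Nr = R.sum()
    f = {k: 0.0 for k in (
        "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
        "glrlm_lgre", "glrlm_hgre", "glrlm_srlge", "glrlm_srhge",
        "glrlm_lrlge", "glrlm_lrhge")}
    for i in range(Ng):
        for j in range(Nl):
            r = R[i, j]
            gi, lj = i + 1, j + 1
            f["glrlm_sre"] += r / lj**2
            f["glrlm_lre"] += r * lj**2
            f["glrlm_lgre"] += r / gi**2
            f["glrlm_hgre"] += r * gi**2
            f["glrlm_srlge"] += r / (gi**2 * lj**2)
            f["glrlm_srhge"] += r * gi**2 / lj**2
            f["glrlm_lrlge"] += r * lj**2 / gi**2
            f["glrlm_lrhge"] += r * gi**2 * lj**2
    f["glrlm_gln"] = sum(R[i].sum() ** 2 for i in range(Ng))
    f["glrlm_rln"] = sum(R[:, j].sum() ** 2 for j in range(Nl))
    for k in f:
        f[k] /= Nr
    f["glrlm_rp"] = Nr / Np
    return f


def auc_pairs_brute(scores, labels):
    """AUC by exhaustive positive/negative pair comparison (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def kmeans_best_J_brute(values, k):
    """Minimal within-cluster sum of squares over all contiguous partitions
    of the sorted values (optimal 1-D clusters are intervals)."""
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if len(seg) else 0.0

    best = math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        J = sum(sse(vals[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        best = min(best, J)
    return best
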