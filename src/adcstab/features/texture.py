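"""Gray-level texture matrices and their features (2D).

The five families operate on a discretized gray-level image in which pixels
outside the region of interest are 0 and in-mask pixels carry integer levels
>= 1:

* GLCM  — co-occurrence at a fixed distance over the 4 in-plane angles,
  symmetric, features averaged per angle (24 features);
* GLRLM — run lengths along the 4 angles, averaged (16);
* GLSZM — 8-connected iso-level zone sizes, single matrix (16);
* GLDM  — dependence counts in the 8-neighborhood with tolerance alpha,
  the center pixel counted as its own dependency (14);
* NGTDM — per-level absolute deviation from the mean of the in-mask
  8-neighborhood (5).

Degenerate quantities (e.g. correlation of a single-level region) are
returned as NaN so the caller can flag rather than silently zero them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import ExtractionConfig

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

# 4 unique in-plane angles (the opposite directions are covered by symmetry
# for GLCM and by whole-line traversal for GLRLM)
ANGLES_4 = ((0, 1), (1, 1), (1, 0), (1, -1))
NEIGHBORS_8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


def _shifted_views(a: np.ndarray, dr: int, dc: int):
    """Overlapping views (center, neighbor) of ``a`` for offset (dr, dc)."""
    nr, nc = a.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    center = a[r0:r1, c0:c1]
    neighbor = a[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return center, neighbor


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_count_matrices(
    levels: np.ndarray, n_levels: int, distance: int = 1
) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per in-plane angle."""
    mats = []
    for dr, dc in ANGLES_4:
        a, b = _shifted_views(levels, dr * distance, dc * distance)
        sel = (a > 0) & (b > 0)
        idx = (a[sel] - 1) * n_levels + (b[sel] - 1)
        counts = np.bincount(idx, minlength=n_levels * n_levels)
        c = counts.reshape(n_levels, n_levels).astype(float)
        mats.append(c + c.T)
    return mats


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = np.sqrt(np.sum((i - mu_x) ** 2 * px))
    sig_y = np.sqrt(np.sum((i - mu_y) ** 2 * py))

    ii = i[:, None]
    jj = i[None, :]
    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(Ng, dtype=float)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(np.subtract.outer(np.arange(Ng), np.arange(Ng))), P)
    k_sum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, np.add.outer(np.arange(Ng), np.arange(Ng)), P)

    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    hxy = float(-np.sum(_xlog2(P)))
    pxpy = np.outer(px, py)
    sel = (P > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(P[sel] * np.log2(pxpy[sel])))
    hxy2 = float(-np.sum(_xlog2(pxpy)))

    present = px > 0
    if present.sum() > 1:
        # MCC: second-largest eigenvalue of the transition-like matrix Q
        Pp = P[np.ix_(present, present)]
        pxp = px[present]
        pyp = py[present]
        Q = (Pp / pxp[:, None]) @ (Pp / pyp[:, None])
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    diff_avg = float(np.sum(k_diff * p_diff))
    denom_corr = sig_x * sig_y
    correlation = (
        (float(np.sum(ii * jj * P)) - mu_x * mu_y) / denom_corr
        if denom_corr > 0
        else np.nan
    )
    inv_var_sel = np.abs(ii - jj) > 0
    max_h = max(hx, hy)

    return {
        "Autocorrelation": float(np.sum(ii * jj * P)),
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * P)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * P)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * P)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(_xlog2(p_diff))),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + (ii - jj) ** 2 / Ng**2))),
        "Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / Ng))),
        "Imc1": (hxy - hxy1) / max_h if max_h > 0 else 0.0,
        "Imc2": float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0))),
        "InverseVariance": float(
            np.sum(P[inv_var_sel] / (ii - jj)[inv_var_sel] ** 2)
        ),
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(_xlog2(p_sum))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * P)),
    }


def glcm_features(levels: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    n_levels = int(levels.max())
    per_angle = []
    for counts in glcm_count_matrices(levels, n_levels, config.glcm_distance):
        total = counts.sum()
        if total == 0:
            continue
        per_angle.append(_glcm_single(counts / total))
    if not per_angle:
        return {name: np.nan for name in GLCM_NAMES}
    return {
        name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM


def _run_lengths(line: np.ndarray, out: np.ndarray) -> None:
    """Accumulate runs of equal nonzero values of a 1D line into ``out``."""
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    for s, e in zip(starts, ends):
        v = line[s]
        if v > 0:
            out[v - 1, e - s - 1] += 1


def glrlm_count_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrices for the 4 in-plane angles."""
    max_len = max(levels.shape)
    mats = []
    for direction in ANGLES_4:
        R = np.zeros((n_levels, max_len))
        if direction == (0, 1):
            lines = list(levels)
        elif direction == (1, 0):
            lines = list(levels.T)
        elif direction == (1, 1):
            lines = [
                np.diagonal(levels, offset=o)
                for o in range(-levels.shape[0] + 1, levels.shape[1])
            ]
        else:  # (1, -1): anti-diagonals
            flipped = np.fliplr(levels)
            lines = [
                np.diagonal(flipped, offset=o)
                for o in range(-levels.shape[0] + 1, levels.shape[1])
            ]
        for line in lines:
            _run_lengths(np.ascontiguousarray(line), R)
        mats.append(R)
    return mats


def _weighted_stats(P: np.ndarray) -> dict[str, float]:
    """The 16 emphasis/nonuniformity/variance statistics shared by the
    run-length and size-zone families, on an unnormalized (Ng x L) matrix."""
    n_total = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / n_total
    mu_i = float(np.sum(p * i))
    mu_l = float(np.sum(p * l))
    return {
        "small": float(np.sum(P / l**2) / n_total),
        "large": float(np.sum(P * l**2) / n_total),
        "gln": float(np.sum(P.sum(axis=1) ** 2) / n_total),
        "glnn": float(np.sum(P.sum(axis=1) ** 2) / n_total**2),
        "ln": float(np.sum(P.sum(axis=0) ** 2) / n_total),
        "lnn": float(np.sum(P.sum(axis=0) ** 2) / n_total**2),
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "lv": float(np.sum(p * (l - mu_l) ** 2)),
        "entropy": float(-np.sum(_xlog2(p))),
        "lgl": float(np.sum(P / i**2) / n_total),
        "hgl": float(np.sum(P * i**2) / n_total),
        "sl": float(np.sum(P / (i**2 * l**2)) / n_total),
        "sh": float(np.sum(P * i**2 / l**2) / n_total),
        "ll": float(np.sum(P * l**2 / i**2) / n_total),
        "lh": float(np.sum(P * i**2 * l**2) / n_total),
        "n_total": float(n_total),
    }


def glrlm_features(levels: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    n_levels = int(levels.max())
    n_px = int((levels > 0).sum())
    per_angle = []
    for R in glrlm_count_matrices(levels, n_levels):
        if R.sum() == 0:
            continue
        s = _weighted_stats(R)
        per_angle.append(
            {
                "ShortRunEmphasis": s["small"],
                "LongRunEmphasis": s["large"],
                "GrayLevelNonUniformity": s["gln"],
                "GrayLevelNonUniformityNormalized": s["glnn"],
                "RunLengthNonUniformity": s["ln"],
                "RunLengthNonUniformityNormalized": s["lnn"],
                "RunPercentage": s["n_total"] / n_px,
                "GrayLevelVariance": s["glv"],
                "RunVariance": s["lv"],
                "RunEntropy": s["entropy"],
                "LowGrayLevelRunEmphasis": s["lgl"],
                "HighGrayLevelRunEmphasis": s["hgl"],
                "ShortRunLowGrayLevelEmphasis": s["sl"],
                "ShortRunHighGrayLevelEmphasis": s["sh"],
                "LongRunLowGrayLevelEmphasis": s["ll"],
                "LongRunHighGrayLevelEmphasis": s["lh"],
            }
        )
    return {
        name: float(np.mean([f[name] for f in per_angle])) for name in GLRLM_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM


def glszm_count_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix; zones are 8-connected iso-level regions."""
    structure = np.ones((3, 3), dtype=int)
    zone_sizes: list[tuple[int, int]] = []
    for g in np.unique(levels[levels > 0]):
        labeled, n_zones = ndimage.label(levels == g, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zone_sizes.extend((int(g), int(sz)) for sz in sizes)
    max_size = max(sz for _, sz in zone_sizes)
    P = np.zeros((n_levels, max_size))
    for g, sz in zone_sizes:
        P[g - 1, sz - 1] += 1
    return P


def glszm_features(levels: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    n_levels = int(levels.max())
    n_px = int((levels > 0).sum())
    P = glszm_count_matrix(levels, n_levels)
    s = _weighted_stats(P)
    return {
        "SmallAreaEmphasis": s["small"],
        "LargeAreaEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "SizeZoneNonUniformity": s["ln"],
        "SizeZoneNonUniformityNormalized": s["lnn"],
        "ZonePercentage": s["n_total"] / n_px,
        "GrayLevelVariance": s["glv"],
        "ZoneVariance": s["lv"],
        "ZoneEntropy": s["entropy"],
        "LowGrayLevelZoneEmphasis": s["lgl"],
        "HighGrayLevelZoneEmphasis": s["hgl"],
        "SmallAreaLowGrayLevelEmphasis": s["sl"],
        "SmallAreaHighGrayLevelEmphasis": s["sh"],
        "LargeAreaLowGrayLevelEmphasis": s["ll"],
        "LargeAreaHighGrayLevelEmphasis": s["lh"],
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_count_matrix(
    levels: np.ndarray, n_levels: int, alpha: float = 0.0
) -> np.ndarray:
    """Dependence count matrix.

    A neighbor is dependent when |level difference| <= alpha; the dependence
    size of a pixel is 1 (itself) plus its dependent in-mask 8-neighbors, so
    sizes run 1..9 and the matrix row sums equal the per-level pixel counts.
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=int)
    for dr, dc in NEIGHBORS_8:
        c_lev, n_lev = _shifted_views(levels, dr, dc)
        c_dep, _ = _shifted_views(dep, dr, dc)
        c_dep += (c_lev > 0) & (n_lev > 0) & (np.abs(c_lev - n_lev) <= alpha)
    sizes = dep[mask] + 1
    i = levels[mask]
    P = np.zeros((n_levels, 9))
    np.add.at(P, (i - 1, sizes - 1), 1.0)
    return P


def gldm_features(levels: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    n_levels = int(levels.max())
    P = gldm_count_matrix(levels, n_levels, config.gldm_alpha)
    s = _weighted_stats(P)
    return {
        "SmallDependenceEmphasis": s["small"],
        "LargeDependenceEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "DependenceNonUniformity": s["ln"],
        "DependenceNonUniformityNormalized": s["lnn"],
        "GrayLevelVariance": s["glv"],
        "DependenceVariance": s["lv"],
        "DependenceEntropy": s["entropy"],
        "LowGrayLevelEmphasis": s["lgl"],
        "HighGrayLevelEmphasis": s["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": s["sl"],
        "SmallDependenceHighGrayLevelEmphasis": s["sh"],
        "LargeDependenceLowGrayLevelEmphasis": s["ll"],
        "LargeDependenceHighGrayLevelEmphasis": s["lh"],
    }


# ---------------------------------------------------------------------------
# NGTDM

#: conventional stand-in for an infinite coarseness (fully uniform region)
COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray, n_levels: int):
    """Per-level (n_i, p_i, s_i): pixel count, probability, and summed
    absolute deviation from the mean of the in-mask 8-neighborhood.

    Pixels with no in-mask neighbor contribute 0 to s_i but count in n_i.
    """
    mask = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=float)
    nbr_cnt = np.zeros(levels.shape, dtype=int)
    for dr, dc in NEIGHBORS_8:
        c_lev, n_lev = _shifted_views(levels, dr, dc)
        c_sum, _ = _shifted_views(nbr_sum, dr, dc)
        c_cnt, _ = _shifted_views(nbr_cnt, dr, dc)
        has = (c_lev > 0) & (n_lev > 0)
        c_sum += np.where(has, n_lev, 0)
        c_cnt += has
    dev = np.zeros(levels.shape, dtype=float)
    ok = mask & (nbr_cnt > 0)
    dev[ok] = np.abs(levels[ok] - nbr_sum[ok] / nbr_cnt[ok])
    n_i = np.bincount(levels[mask], minlength=n_levels + 1)[1:].astype(float)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, levels[mask] - 1, dev[mask])
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


def ngtdm_features(levels: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    n_levels = int(levels.max())
    n_i, p_i, s_i = ngtdm_table(levels, n_levels)
    n_total = n_i.sum()
    ivec = np.arange(1, n_levels + 1, dtype=float)
    present = p_i > 0
    n_gp = int(present.sum())

    pi, si, iv = p_i[present], s_i[present], ivec[present]
    ps = float(np.sum(p_i * s_i))

    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if n_gp > 1:
        pij = pi[:, None] * pi[None, :]
        dij = iv[:, None] - iv[None, :]
        contrast = float(
            np.sum(pij * dij**2) / (n_gp * (n_gp - 1)) * (s_i.sum() / n_total)
        )
        busy_denom = float(np.sum(np.abs(np.subtract.outer(iv * pi, iv * pi))))
        busyness = ps / busy_denom if busy_denom > 0 else 0.0
        num = (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / (
            pi[:, None] + pi[None, :]
        )
        complexity = float(np.sum(np.abs(dij) * num) / n_total)
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((pi[:, None] + pi[None, :]) * dij**2)) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
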