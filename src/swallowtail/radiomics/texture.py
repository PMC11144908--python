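"""Gray-level texture-matrix features, IBSI definitions.

Five families operate on the fixed-bin-width discretized ROI:

* GLCM — symmetric co-occurrence matrices over the 13 unique 3D
  direction offsets at distance 1; features averaged over directions.
* GLRLM — run-length matrices per direction, averaged likewise.
* GLSZM — size-zone matrix with 26-connected zones.
* GLDM — dependence matrix, 26-neighborhood, tolerance alpha = 0;
  the dependence size counts the center voxel plus its equal-level
  neighbors.
* NGTDM — neighborhood gray-tone difference matrix, 26-neighborhood.

Degenerate ROIs (a single gray level, too few voxels for a direction)
return the documented fallback values rather than NaN: correlation-type
GLCM features fall back to 1, information-measure features to 0, and
NGTDM coarseness to 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizedROI", "discretize",
    "glcm_features", "glrlm_features", "glszm_features",
    "gldm_features", "ngtdm_features",
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
]

# one representative of each +/- offset pair, lexicographically positive
OFFSETS_13 = [
    off for off in product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
]
OFFSETS_26 = [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

COARSENESS_CAP = 1e6


@dataclass
class DiscretizedROI:
    """Gray levels 1..n_levels on mask voxels, 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(volume, mask, bin_width: float = 25.0) -> DiscretizedROI:
    """Fixed-bin-width discretization: level = floor((v - min)/w) + 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intensity = getattr(volume, "intensity", volume)
    intensity = np.asarray(intensity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = intensity[mask]
    levels = np.zeros(intensity.shape, dtype=np.int64)
    levels[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(levels, mask, int(levels.max()), float(bin_width))


def _pair_slices(shape, off):
    a, b = [], []
    for n, o in zip(shape, off):
        a.append(slice(max(0, -o), n - max(0, o)))
        b.append(slice(max(0, o), n - max(0, -o)))
    return tuple(a), tuple(b)


def _masked_log2(p):
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


# ---------------------------------------------------------------- GLCM

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


def glcm_matrix(roi: DiscretizedROI, off) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one offset."""
    ng = roi.n_levels
    sa, sb = _pair_slices(roi.levels.shape, off)
    valid = roi.mask[sa] & roi.mask[sb]
    a = roi.levels[sa][valid] - 1
    b = roi.levels[sb][valid] - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sig_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sig_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    # difference and sum marginals
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    diff_avg = float(k_diff @ p_diff)

    hx = float(-(px * _masked_log2(px)).sum())
    hy = float(-(py * _masked_log2(py)).sum())
    hxy = float(-(p * _masked_log2(p)).sum())
    pxpy = np.outer(px, py)
    lg = _masked_log2(pxpy)
    hxy1 = float(-(p * lg).sum())
    hxy2 = float(-(pxpy * lg).sum())

    if sig_x > 0 and sig_y > 0:
        correlation = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    occ = px > 0
    if occ.sum() > 1:
        ps = p[np.ix_(occ, occ)]
        q = np.einsum("ik,jk->ij", ps, ps / ps.sum(axis=0)[None, :]) / ps.sum(axis=1)[
            :, None
        ]
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    offdiag = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff * _masked_log2(p_diff)).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 @ p_diff)),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(k_sum @ p_sum),
        "SumEntropy": float(-(p_sum * _masked_log2(p_sum)).sum()),
        "SumSquares": float(((i - mu_x) ** 2) @ px),
    }


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """24 GLCM features averaged over the 13 unique 3D directions."""
    if roi.n_voxels < 2:
        raise ValueError("GLCM needs at least 2 mask voxels")
    per_dir = []
    for off in OFFSETS_13:
        p = glcm_matrix(roi, off)
        if p.sum() > 0:
            per_dir.append(_glcm_single(p))
    if not per_dir:  # no voxel pair in any direction
        per_dir = [_glcm_single(np.ones((1, 1)))]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# --------------------------------------------------- run/zone/dependence

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _row_col_stats(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Shared statistics of a (gray level x size) count matrix."""
    n = counts.sum()
    p = counts / n
    ng, js = counts.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, js + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "small": float((p / jj**2).sum()),
        "large": float((p * jj**2).sum()),
        "low": float((p / ii**2).sum()),
        "high": float((p * ii**2).sum()),
        "small_low": float((p / (ii**2 * jj**2)).sum()),
        "small_high": float((p * ii**2 / jj**2).sum()),
        "large_low": float((p * jj**2 / ii**2).sum()),
        "large_high": float((p * ii**2 * jj**2).sum()),
        "gln": float((row**2).sum() / n),
        "glnn": float((row**2).sum() / n**2),
        "sn": float((col**2).sum() / n),
        "snn": float((col**2).sum() / n**2),
        "percentage": float(n / n_voxels),
        "gl_var": float((((ii - mu_i) ** 2) * p).sum()),
        "size_var": float((((jj - mu_j) ** 2) * p).sum()),
        "entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
    }


def glrlm_matrix(roi: DiscretizedROI, off) -> np.ndarray:
    """Run-length count matrix (gray level x run length) for one direction."""
    idx = np.argwhere(roi.mask)
    lv = roi.levels[roi.mask]
    r, c, z = idx.T
    o = off
    line_id = np.stack(
        [c * o[0] - r * o[1], z * o[0] - r * o[2], z * o[1] - c * o[2]], axis=1
    )
    t = r * o[0] + c * o[1] + z * o[2]
    step = o[0] ** 2 + o[1] ** 2 + o[2] ** 2
    order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
    lv_s, t_s, lid_s = lv[order], t[order], line_id[order]
    new_run = np.ones(lv.size, dtype=bool)
    if lv.size > 1:
        same_line = (lid_s[1:] == lid_s[:-1]).all(axis=1)
        contiguous = (t_s[1:] - t_s[:-1]) == step
        same_level = lv_s[1:] == lv_s[:-1]
        new_run[1:] = ~(same_line & contiguous & same_level)
    run_id = np.cumsum(new_run) - 1
    run_level = lv_s[new_run]
    run_len = np.bincount(run_id)
    ng, lmax = roi.n_levels, int(run_len.max())
    counts = np.zeros((ng, lmax))
    np.add.at(counts, (run_level - 1, run_len - 1), 1.0)
    return counts


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 13 unique directions."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    per_dir = []
    for off in OFFSETS_13:
        s = _row_col_stats(glrlm_matrix(roi, off), roi.n_voxels)
        per_dir.append({
            "GrayLevelNonUniformity": s["gln"],
            "GrayLevelNonUniformityNormalized": s["glnn"],
            "GrayLevelVariance": s["gl_var"],
            "HighGrayLevelRunEmphasis": s["high"],
            "LongRunEmphasis": s["large"],
            "LongRunHighGrayLevelEmphasis": s["large_high"],
            "LongRunLowGrayLevelEmphasis": s["large_low"],
            "LowGrayLevelRunEmphasis": s["low"],
            "RunEntropy": s["entropy"],
            "RunLengthNonUniformity": s["sn"],
            "RunLengthNonUniformityNormalized": s["snn"],
            "RunPercentage": s["percentage"],
            "RunVariance": s["size_var"],
            "ShortRunEmphasis": s["small"],
            "ShortRunHighGrayLevelEmphasis": s["small_high"],
            "ShortRunLowGrayLevelEmphasis": s["small_low"],
        })
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


def glszm_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Size-zone count matrix (gray level x zone size), 26-connected."""
    zones = []  # (level, size)
    for level in np.unique(roi.masked_levels):
        labeled, n = ndimage.label(roi.levels == level, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((level, s) for s in sizes)
    ng = roi.n_levels
    smax = max(s for _, s in zones)
    counts = np.zeros((ng, smax))
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return counts


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    s = _row_col_stats(glszm_matrix(roi), roi.n_voxels)
    return {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["gl_var"],
        "HighGrayLevelZoneEmphasis": s["high"],
        "LargeAreaEmphasis": s["large"],
        "LargeAreaHighGrayLevelEmphasis": s["large_high"],
        "LargeAreaLowGrayLevelEmphasis": s["large_low"],
        "LowGrayLevelZoneEmphasis": s["low"],
        "SizeZoneNonUniformity": s["sn"],
        "SizeZoneNonUniformityNormalized": s["snn"],
        "SmallAreaEmphasis": s["small"],
        "SmallAreaHighGrayLevelEmphasis": s["small_high"],
        "SmallAreaLowGrayLevelEmphasis": s["small_low"],
        "ZoneEntropy": s["entropy"],
        "ZonePercentage": s["percentage"],
        "ZoneVariance": s["size_var"],
    }


def gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (gray level x dependence size).

    The dependence size of a voxel is 1 (itself) plus the number of
    26-neighbors inside the mask whose level differs by at most alpha.
    """
    dep = np.zeros(roi.levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sa, sb = _pair_slices(roi.levels.shape, off)
        ok = (
            roi.mask[sa]
            & roi.mask[sb]
            & (np.abs(roi.levels[sa] - roi.levels[sb]) <= alpha)
        )
        dep[sa] += ok
    sizes = dep[roi.mask] + 1
    lv = roi.masked_levels
    counts = np.zeros((roi.n_levels, int(sizes.max())))
    np.add.at(counts, (lv - 1, sizes - 1), 1.0)
    return counts


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    s = _row_col_stats(gldm_matrix(roi, alpha), roi.n_voxels)
    return {
        "DependenceEntropy": s["entropy"],
        "DependenceNonUniformity": s["sn"],
        "DependenceNonUniformityNormalized": s["snn"],
        "DependenceVariance": s["size_var"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelVariance": s["gl_var"],
        "HighGrayLevelEmphasis": s["high"],
        "LargeDependenceEmphasis": s["large"],
        "LargeDependenceHighGrayLevelEmphasis": s["large_high"],
        "LargeDependenceLowGrayLevelEmphasis": s["large_low"],
        "LowGrayLevelEmphasis": s["low"],
        "SmallDependenceEmphasis": s["small"],
        "SmallDependenceHighGrayLevelEmphasis": s["small_high"],
        "SmallDependenceLowGrayLevelEmphasis": s["small_low"],
    }


def ngtdm_features(roi: DiscretizedROI) -> dict[str, float]:
    """5 neighborhood gray-tone difference features (26-neighborhood)."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    nb_sum = np.zeros(roi.levels.shape)
    nb_cnt = np.zeros(roi.levels.shape)
    for off in OFFSETS_26:
        sa, sb = _pair_slices(roi.levels.shape, off)
        ok = roi.mask[sa] & roi.mask[sb]
        nb_sum[sa] += np.where(ok, roi.levels[sb], 0)
        nb_cnt[sa] += ok
    has_nb = roi.mask & (nb_cnt > 0)
    lv = roi.levels[has_nb]
    avg = nb_sum[has_nb] / nb_cnt[has_nb]
    nvp = lv.size
    if nvp == 0:
        return {"Busyness": 0.0, "Coarseness": COARSENESS_CAP,
                "Complexity": 0.0, "Contrast": 0.0, "Strength": 0.0}

    ng = roi.n_levels
    n_i = np.bincount(lv - 1, minlength=ng).astype(float)
    s_i = np.bincount(lv - 1, weights=np.abs(lv - avg), minlength=ng)
    p_i = n_i / nvp
    i = np.arange(1, ng + 1, dtype=float)
    occ = p_i > 0
    ngp = int(occ.sum())

    ps = float(p_i @ s_i)
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    io, po, so = i[occ], p_i[occ], s_i[occ]
    di = io[:, None] - io[None, :]
    if ngp > 1:
        contrast = (
            (po[:, None] * po[None, :] * di**2).sum() / (ngp * (ngp - 1))
        ) * (so.sum() / nvp)
        denom_busy = np.abs(io * po - (io * po)[:, None]).sum()
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = (
            np.abs(di)
            * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
            / (po[:, None] + po[None, :])
        ).sum() / nvp
        denom_strength = so.sum()
        strength = (
            ((po[:, None] + po[None, :]) * di**2).sum() / denom_strength
            if denom_strength > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }
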