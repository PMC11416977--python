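"""Gray-level texture-matrix features: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All five families operate on a :class:`~.discretize.DiscretizedRoi`.  The
directional families (GLCM, GLRLM) build one matrix per unique distance-1
3-D direction (13 of them) and average the feature values over directions,
the convention of the CT radiomics toolchain this package mirrors.  GLSZM
and GLDM use 26-connectivity; NGTDM averages over in-ROI 26-neighbors.

Degenerate-value policy: every 0/0 encountered on a constant or
single-voxel ROI resolves to a documented constant (e.g. GLCM Correlation
and MCC are 1 when only one gray level occurs, entropies are 0, NGTDM
Coarseness is capped at 1e6), so downstream feature matrices are always
finite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedRoi

__all__ = [
    "DIRECTIONS_3D",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "glcm_matrices",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_matrix",
    "ngtdm_features",
    "gldm_matrix",
    "gldm_features",
]

COARSENESS_CAP = 1e6

# the 13 unique 3-D offsets at Chebyshev distance 1 (first nonzero
# component positive; the opposite offsets are covered by symmetry)
DIRECTIONS_3D = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_NEIGHBORS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def _bbox(droi: DiscretizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Levels and mask cropped to the mask's tight bounding box."""
    idx = np.argwhere(droi.mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return droi.levels[sl], droi.mask[sl]


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """out[v] = arr[v + d], padded with ``fill`` outside the grid."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for axis, dd in enumerate(d):
        n = arr.shape[axis]
        if dd >= 0:
            src.append(slice(dd, n))
            dst.append(slice(0, n - dd))
        else:
            src.append(slice(0, n + dd))
            dst.append(slice(-dd, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# --------------------------------------------------------------------------
# GLCM


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
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def glcm_matrices(
    droi: DiscretizedRoi, distances=(1,), symmetric: bool = True
) -> list[np.ndarray]:
    """Normalized co-occurrence matrices, one per direction (and distance)."""
    levels, mask = _bbox(droi)
    ng = droi.ng
    mats = []
    for dist in distances:
        for d in DIRECTIONS_3D:
            off = tuple(dd * dist for dd in d)
            lv2 = _shift(levels, off)
            ok = mask & (lv2 > 0)
            a = levels[ok] - 1
            b = lv2[ok] - 1
            counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
            counts = counts.astype(np.float64)
            if symmetric:
                counts = counts + counts.T
            total = counts.sum()
            mats.append(counts / total if total > 0 else counts)
    return mats


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = np.sqrt(float((((i - mux) ** 2) * px).sum()))
    sigy = np.sqrt(float((((i - muy) ** 2) * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount((I + J).ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(np.abs(I - J).ravel(), weights=P.ravel(), minlength=ng)[:ng]

    autocorr = float((I * J * P).sum())
    corr = 1.0 if sigx * sigy == 0 else (autocorr - mux * muy) / (sigx * sigy)

    da = float((k_diff * p_diff).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    hxy = float(-_xlog2(P).sum())
    pxpy = np.outer(px, py)
    mask_joint = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[mask_joint] * np.log2(pxpy[mask_joint])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    imc1 = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    occupied = px > 0
    if occupied.sum() <= 1:
        mcc = 1.0
    else:
        Psub = P[np.ix_(occupied, occupied)]
        pxs = px[occupied]
        pys = py[occupied]
        # Q(i, j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        Q = (Psub / pxs[:, None]) @ (Psub / pys[:, None]).T
        eig = np.linalg.eigvals(Q)
        eig = np.sort(np.abs(eig))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if len(eig) > 1 else 1.0

    nz_diff = k_diff >= 1
    inv_var = float((p_diff[nz_diff] / (k_diff[nz_diff] ** 2)).sum())

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float((((I + J - mux - muy) ** 4) * P).sum()),
        "ClusterShade": float((((I + J - mux - muy) ** 3) * P).sum()),
        "ClusterTendency": float((((I + J - mux - muy) ** 2) * P).sum()),
        "Contrast": float((((I - J) ** 2) * P).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mux,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumSquares": float((((I - mux) ** 2) * P).sum()),
    }


def glcm_features(
    droi: DiscretizedRoi, distances=(1,), symmetric: bool = True
) -> dict[str, float]:
    """The 24 GLCM features, averaged over the 13 distance-1 directions."""
    mats = glcm_matrices(droi, distances, symmetric)
    per_dir = [_glcm_single(P) for P in mats]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


# --------------------------------------------------------------------------
# GLRLM


GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def _runs_along(levels: np.ndarray, mask: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, run length) of every maximal run along direction d."""
    lv2 = _shift(levels, d)
    same = mask & (lv2 == levels) & (lv2 > 0)  # pair (v, v+d) continues a run
    # chain[v] = remaining run length starting at v, by backward recursion
    # along the first axis with a nonzero (positive) direction component
    axis = next(a for a in range(3) if d[a] != 0)
    da = d[axis]
    rest = tuple(dd for a, dd in enumerate(d) if a != axis)
    C = np.moveaxis(mask.astype(np.int64).copy(), axis, 0)
    S = np.moveaxis(same, axis, 0)
    for idx in reversed(range(C.shape[0] - da)):
        nxt = _shift(C[idx + da], rest)
        C[idx] = np.where(S[idx], 1 + nxt, C[idx])
    chain = np.moveaxis(C, 0, axis)
    # a run starts where the predecessor does not continue into v
    cont_into = _shift(same, tuple(-dd for dd in d))  # same[v - d]
    start = mask & ~cont_into
    return levels[start], chain[start]


def glrlm_matrices(droi: DiscretizedRoi, directions=None) -> list[np.ndarray]:
    """Run-length matrices (gray level x run length), one per direction."""
    levels, mask = _bbox(droi)
    dirs = DIRECTIONS_3D if directions is None else tuple(directions)
    ng = droi.ng
    out = []
    max_len = max(levels.shape)
    for d in dirs:
        g, ln = _runs_along(levels, mask, d)
        R = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(R, (g - 1, ln - 1), 1.0)
        out.append(R)
    return out


def _rlm_style_features(R: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature formulas for run-length / size-zone style matrices.

    ``R`` is counts over (gray level i, size j); ``kind`` selects the
    family's naming ('run' or 'zone').
    """
    nr = R.sum()
    ng, nj = R.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nj + 1, dtype=np.float64)
    p = R / nr
    pg = p.sum(axis=1)  # marginal over sizes
    pj = p.sum(axis=0)
    mu_i = float((i * pg).sum())
    mu_j = float((j * pj).sum())
    I2 = i**2
    J2 = j**2
    vals = {
        "Short": float((p / J2[None, :]).sum()),
        "Long": float((p * J2[None, :]).sum()),
        "GLN": float((R.sum(axis=1) ** 2).sum() / nr),
        "GLNN": float((pg**2).sum()),
        "SizeN": float((R.sum(axis=0) ** 2).sum() / nr),
        "SizeNN": float((pj**2).sum()),
        "Pct": float(nr / n_voxels),
        "GLV": float((pg * (i - mu_i) ** 2).sum()),
        "SizeV": float((pj * (j - mu_j) ** 2).sum()),
        "Entropy": float(-_xlog2(p).sum()),
        "Low": float((p / I2[:, None]).sum()),
        "High": float((p * I2[:, None]).sum()),
        "ShortLow": float((p / np.outer(I2, J2)).sum()),
        "ShortHigh": float((p * I2[:, None] / J2[None, :]).sum()),
        "LongLow": float((p * J2[None, :] / I2[:, None]).sum()),
        "LongHigh": float((p * np.outer(I2, J2)).sum()),
    }
    if kind == "run":
        return {
            "GrayLevelNonUniformity": vals["GLN"],
            "GrayLevelNonUniformityNormalized": vals["GLNN"],
            "GrayLevelVariance": vals["GLV"],
            "HighGrayLevelRunEmphasis": vals["High"],
            "LongRunEmphasis": vals["Long"],
            "LongRunHighGrayLevelEmphasis": vals["LongHigh"],
            "LongRunLowGrayLevelEmphasis": vals["LongLow"],
            "LowGrayLevelRunEmphasis": vals["Low"],
            "RunEntropy": vals["Entropy"],
            "RunLengthNonUniformity": vals["SizeN"],
            "RunLengthNonUniformityNormalized": vals["SizeNN"],
            "RunPercentage": vals["Pct"],
            "RunVariance": vals["SizeV"],
            "ShortRunEmphasis": vals["Short"],
            "ShortRunHighGrayLevelEmphasis": vals["ShortHigh"],
            "ShortRunLowGrayLevelEmphasis": vals["ShortLow"],
        }
    return {
        "GrayLevelNonUniformity": vals["GLN"],
        "GrayLevelNonUniformityNormalized": vals["GLNN"],
        "GrayLevelVariance": vals["GLV"],
        "HighGrayLevelZoneEmphasis": vals["High"],
        "LargeAreaEmphasis": vals["Long"],
        "LargeAreaHighGrayLevelEmphasis": vals["LongHigh"],
        "LargeAreaLowGrayLevelEmphasis": vals["LongLow"],
        "LowGrayLevelZoneEmphasis": vals["Low"],
        "SizeZoneNonUniformity": vals["SizeN"],
        "SizeZoneNonUniformityNormalized": vals["SizeNN"],
        "SmallAreaEmphasis": vals["Short"],
        "SmallAreaHighGrayLevelEmphasis": vals["ShortHigh"],
        "SmallAreaLowGrayLevelEmphasis": vals["ShortLow"],
        "ZoneEntropy": vals["Entropy"],
        "ZonePercentage": vals["Pct"],
        "ZoneVariance": vals["SizeV"],
    }


def glrlm_features(droi: DiscretizedRoi, directions=None) -> dict[str, float]:
    """The 16 GLRLM features, averaged over the 13 directions."""
    mats = glrlm_matrices(droi, directions)
    n = droi.n_voxels
    per_dir = [_rlm_style_features(R, n, "run") for R in mats]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}


# --------------------------------------------------------------------------
# GLSZM


GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(droi: DiscretizedRoi) -> np.ndarray:
    """Size-zone matrix (gray level x zone size), 26-connected zones."""
    levels, mask = _bbox(droi)
    ng = droi.ng
    n = int(mask.sum())
    zones: list[tuple[int, int]] = []
    for g in np.unique(levels[mask]):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    Z = np.zeros((ng, n), dtype=np.float64)
    for g, s in zones:
        Z[g - 1, s - 1] += 1.0
    return Z


def glszm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 16 GLSZM features (single matrix; zones have no direction)."""
    Z = glszm_matrix(droi)
    return _rlm_style_features(Z, droi.n_voxels, "zone")


# --------------------------------------------------------------------------
# NGTDM


NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_K26 = np.ones((3, 3, 3))
_K26[1, 1, 1] = 0.0


def ngtdm_matrix(droi: DiscretizedRoi) -> np.ndarray:
    """Neighborhood gray-tone difference table: rows (n_i, p_i, s_i).

    Row i (gray level i+1) holds the voxel count n_i, probability p_i and
    accumulated absolute difference s_i between level and the mean of the
    in-ROI 26-neighbors.  Voxels with no in-ROI neighbor are excluded.
    """
    levels, mask = _bbox(droi)
    ng = droi.ng
    mf = mask.astype(np.float64)
    nb_sum = ndimage.convolve(levels * mf, _K26, mode="constant")
    nb_cnt = ndimage.convolve(mf, _K26, mode="constant")
    valid = mask & (nb_cnt > 0)
    A = np.zeros_like(nb_sum)
    A[valid] = nb_sum[valid] / nb_cnt[valid]
    g = levels[valid]
    diff = np.abs(g - A[valid])
    n_i = np.bincount(g - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(g - 1, weights=diff, minlength=ng)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return np.stack([n_i, p_i, s_i], axis=1)


def ngtdm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The five NGTDM features."""
    tab = ngtdm_matrix(droi)
    n_i, p_i, s_i = tab[:, 0], tab[:, 1], tab[:, 2]
    ng = len(p_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    n_total = n_i.sum()

    ps = float((p_i * s_i).sum())
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP

    if ngp <= 1 or n_total == 0:
        contrast = 0.0
    else:
        pij = np.outer(p_i, p_i)
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(
            (pij * dij2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_total)
        )

    ip = i * p_i
    denom_busy = float(
        np.abs(ip[present, None] - ip[None, present]).sum()
    )
    busyness = ps / denom_busy if denom_busy > 0 else 0.0

    complexity = 0.0
    strength = 0.0
    if ngp >= 1 and n_total > 0:
        ii = i[present]
        pp = p_i[present]
        ss = s_i[present]
        absdiff = np.abs(ii[:, None] - ii[None, :])
        num = pp[:, None] * ss[:, None] + pp[None, :] * ss[None, :]
        den = pp[:, None] + pp[None, :]
        complexity = float((absdiff * num / den).sum() / n_total)
        s_sum = float(ss.sum())
        if s_sum > 0:
            strength = float((den * (ii[:, None] - ii[None, :]) ** 2).sum() / s_sum)

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# --------------------------------------------------------------------------
# GLDM


GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_matrix(droi: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[g, d]: d = number of 26-neighbors within alpha.

    The dependence count d ranges 0..26 (an isolated voxel sits in the
    d = 0 column); emphasis formulas use the dependence *size* d + 1.
    """
    levels, mask = _bbox(droi)
    ng = droi.ng
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _NEIGHBORS_26:
        lv2 = _shift(levels, d)
        dep += (mask & (lv2 > 0) & (np.abs(lv2 - levels) <= alpha)).astype(np.int64)
    g = levels[mask] - 1
    dd = dep[mask]
    P = np.zeros((ng, 27), dtype=np.float64)
    np.add.at(P, (g, dd), 1.0)
    return P[:, : dd.max() + 1]


def gldm_features(droi: DiscretizedRoi, alpha: int = 0) -> dict[str, float]:
    """The 14 GLDM features."""
    P = gldm_matrix(droi, alpha)
    nz = P.sum()
    ng, nd = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nd + 1, dtype=np.float64)  # dependence size = count + 1
    p = P / nz
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float((i * pg).sum())
    mu_j = float((j * pd).sum())
    I2, J2 = i**2, j**2
    return {
        "DependenceEntropy": float(-_xlog2(p).sum()),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum()),
        "DependenceVariance": float((pd * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelVariance": float((pg * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * I2[:, None]).sum()),
        "LargeDependenceEmphasis": float((p * J2[None, :]).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * np.outer(I2, J2)).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * J2[None, :] / I2[:, None]).sum()),
        "LowGrayLevelEmphasis": float((p / I2[:, None]).sum()),
        "SmallDependenceEmphasis": float((p / J2[None, :]).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * I2[:, None] / J2[None, :]).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / np.outer(I2, J2)).sum()),
    }
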