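"""Gray-level texture matrices and the 75 texture features.

Conventions (IBSI-aligned):

* input is a discretized level image, levels 1..Ng inside the mask and 0
  outside;
* GLCM: symmetric, distance 1, the 13 unique 3D directions, features
  computed per direction and averaged;
* GLRLM: run lengths along the same 13 directions, features averaged;
* GLDM: distance 1, dependence threshold α = 0; the dependence size of a
  voxel is 1 + the number of 26-neighbors inside the mask whose level
  differs by at most α;
* GLSZM: zones are 26-connected components of equal level;
* NGTDM: distance 1, neighborhood average over in-mask 26-neighbors.

Degenerate quantities return fixed conventional values (correlation and
MCC → 1 for a single-level region, NGTDM coarseness capped at 1e6), noted
per feature in the code.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "DIRECTIONS_3D", "glcm_matrices", "gldm_matrix", "glrlm_matrices",
    "glszm_matrix", "ngtdm_table", "texture_features",
    "glcm_features", "gldm_features", "glrlm_features", "glszm_features",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)

#: The 13 unique (up to sign) 3D neighbor directions at distance 1.
DIRECTIONS_3D = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) > (0, 0, 0)],
    dtype=np.int64,
)

_NEIGHBORS_26 = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)


@njit(cache=True)
def _glcm_kernel(levels, ng, offsets):
    nx, ny, nz = levels.shape
    nd = offsets.shape[0]
    out = np.zeros((nd, ng, ng), dtype=np.float64)
    for d in range(nd):
        ox, oy, oz = offsets[d]
        for x in range(nx):
            x2 = x + ox
            if x2 < 0 or x2 >= nx:
                continue
            for y in range(ny):
                y2 = y + oy
                if y2 < 0 or y2 >= ny:
                    continue
                for z in range(nz):
                    z2 = z + oz
                    if z2 < 0 or z2 >= nz:
                        continue
                    i = levels[x, y, z]
                    j = levels[x2, y2, z2]
                    if i > 0 and j > 0:
                        out[d, i - 1, j - 1] += 1.0
                        out[d, j - 1, i - 1] += 1.0
    return out


@njit(cache=True)
def _gldm_kernel(levels, ng, neighbors, alpha):
    nx, ny, nz = levels.shape
    out = np.zeros((ng, 28), dtype=np.float64)  # dependence size 1..27
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                dep = 1
                for k in range(neighbors.shape[0]):
                    x2 = x + neighbors[k, 0]
                    y2 = y + neighbors[k, 1]
                    z2 = z + neighbors[k, 2]
                    if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                        j = levels[x2, y2, z2]
                        if j > 0 and abs(i - j) <= alpha:
                            dep += 1
                out[i - 1, dep] += 1.0
    return out


@njit(cache=True)
def _glrlm_kernel(levels, ng, offsets, max_len):
    nx, ny, nz = levels.shape
    nd = offsets.shape[0]
    out = np.zeros((nd, ng, max_len), dtype=np.float64)
    for d in range(nd):
        ox, oy, oz = offsets[d]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    i = levels[x, y, z]
                    if i == 0:
                        continue
                    # run start: predecessor along −d is outside or different
                    px, py, pz = x - ox, y - oy, z - oz
                    if (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                            and levels[px, py, pz] == i):
                        continue
                    length = 1
                    cx, cy, cz = x + ox, y + oy, z + oz
                    while (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
                           and levels[cx, cy, cz] == i):
                        length += 1
                        cx += ox
                        cy += oy
                        cz += oz
                    out[d, i - 1, min(length, max_len) - 1] += 1.0
    return out


@njit(cache=True)
def _ngtdm_kernel(levels, ng, neighbors):
    nx, ny, nz = levels.shape
    s = np.zeros(ng, dtype=np.float64)
    n = np.zeros(ng, dtype=np.float64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                total = 0.0
                count = 0
                for k in range(neighbors.shape[0]):
                    x2 = x + neighbors[k, 0]
                    y2 = y + neighbors[k, 1]
                    z2 = z + neighbors[k, 2]
                    if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                        j = levels[x2, y2, z2]
                        if j > 0:
                            total += j
                            count += 1
                if count > 0:
                    s[i - 1] += abs(i - total / count)
                    n[i - 1] += 1.0
    return s, n


def _crop(levels: np.ndarray) -> np.ndarray:
    """Crop to the bounding box of the nonzero levels (plus nothing)."""
    nz = np.nonzero(levels)
    if len(nz[0]) == 0:
        raise ValueError("empty level image")
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return np.ascontiguousarray(levels[slices])


def glcm_matrices(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric co-occurrence matrices, one per 3D direction: (13, Ng, Ng)."""
    return _glcm_kernel(_crop(levels.astype(np.int64)), ng, DIRECTIONS_3D)


def gldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence matrix (Ng, 27), dependence sizes 1..27."""
    return _gldm_kernel(_crop(levels.astype(np.int64)), ng, _NEIGHBORS_26,
                        alpha)[:, 1:]


def glrlm_matrices(levels: np.ndarray, ng: int) -> np.ndarray:
    """Run-length matrices per direction: (13, Ng, max_run)."""
    lv = _crop(levels.astype(np.int64))
    max_len = int(np.ceil(np.sqrt(np.sum(np.array(lv.shape) ** 2)))) + 1
    return _glrlm_kernel(lv, ng, DIRECTIONS_3D, max_len)


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix (Ng, max_zone); zones are 26-connected components."""
    lv = _crop(levels.astype(np.int64))
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in np.unique(lv):
        if level == 0:
            continue
        labeled, n = ndimage.label(lv == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for sz in sizes:
            zones.append((int(level), int(sz)))
            max_size = max(max_size, int(sz))
    out = np.zeros((ng, max_size), dtype=np.float64)
    for level, sz in zones:
        out[level - 1, sz - 1] += 1.0
    return out


def ngtdm_table(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference sums s_i and counts n_i."""
    return _ngtdm_kernel(_crop(levels.astype(np.int64)), ng, _NEIGHBORS_26)


# ---------------------------------------------------------------------------
# feature formulas


def _xlog2(v: np.ndarray) -> np.ndarray:
    """v·log2(v) with the 0·log(0) = 0 convention."""
    return np.where(v > 0, v * np.log2(np.where(v > 0, v, 1.0)), 0.0)


_GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
]


def glcm_features(mats: np.ndarray) -> dict:
    """24 co-occurrence features, computed per direction then averaged.

    Vectorized over the direction axis; directions with an empty matrix
    (possible for thin regions) are dropped from the average.
    """
    keep = mats.sum(axis=(1, 2)) > 0
    P = mats[keep]
    nd, ng, _ = P.shape
    if nd == 0:
        return {k: 0.0 for k in _GLCM_NAMES}
    p = P / P.sum(axis=(1, 2), keepdims=True)
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=2)  # (nd, ng)
    py = p.sum(axis=1)
    ux = px @ i
    uy = py @ i
    sx = np.sqrt(np.einsum("di,i->d", px, i**2) - ux**2)
    sy = np.sqrt(np.einsum("di,i->d", py, i**2) - uy**2)

    # marginal difference / sum distributions via one-hot matrices
    diff_idx = np.abs(I - J).astype(int)  # 0..ng-1
    sum_idx = (I + J).astype(int) - 2  # 0..2ng-2
    flat = p.reshape(nd, -1)
    p_diff = np.zeros((nd, ng))
    p_sum = np.zeros((nd, 2 * ng - 1))
    for d in range(nd):
        p_diff[d] = np.bincount(diff_idx.ravel(), weights=flat[d], minlength=ng)
        p_sum[d] = np.bincount(sum_idx.ravel(), weights=flat[d],
                               minlength=2 * ng - 1)
    k_diff = np.arange(ng, dtype=float)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)

    hx = -_xlog2(px).sum(axis=1)
    hy = -_xlog2(py).sum(axis=1)
    hxy = -_xlog2(p).sum(axis=(1, 2))
    pxpy = px[:, :, None] * py[:, None, :]
    hxy1 = -np.sum(np.where(p > 0, p * np.log2(pxpy + _EPS), 0.0), axis=(1, 2))
    hxy2 = -_xlog2(pxpy).sum(axis=(1, 2))

    da = (p_diff * k_diff).sum(axis=1)
    num_corr = np.einsum("dij,ij->d", p, I * J) - ux * uy
    ss = sx * sy
    corr = np.where(ss > 0, num_corr / np.where(ss > 0, ss, 1.0), 1.0)

    mcc = np.ones(nd)
    for d in range(nd):
        denom = px[d][:, None] * py[d][None, :]
        ratio = np.where(denom > 0, p[d] / np.where(denom > 0, denom, 1.0), 0.0)
        Q = ratio @ p[d].T
        try:
            eig = np.sort(np.real(np.linalg.eigvals(Q)))
            if len(eig) > 1:
                mcc[d] = np.sqrt(max(eig[-2], 0.0))
        except np.linalg.LinAlgError:
            pass

    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (hxy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    offdiag = np.abs(I - J) > 0
    inv_var = np.einsum(
        "dij,ij->d", p, np.where(offdiag, 1.0 / np.where(offdiag, (I - J) ** 2, 1.0), 0.0)
    )
    cplus = I + J
    vals = {
        "Autocorrelation": np.einsum("dij,ij->d", p, I * J),
        "ClusterProminence": np.einsum(
            "dij,dij->d", p, (cplus[None] - (ux + uy)[:, None, None]) ** 4),
        "ClusterShade": np.einsum(
            "dij,dij->d", p, (cplus[None] - (ux + uy)[:, None, None]) ** 3),
        "ClusterTendency": np.einsum(
            "dij,dij->d", p, (cplus[None] - (ux + uy)[:, None, None]) ** 2),
        "Contrast": np.einsum("dij,ij->d", p, (I - J) ** 2),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -_xlog2(p_diff).sum(axis=1),
        "DifferenceVariance": np.einsum(
            "dk,dk->d", p_diff, (k_diff[None] - da[:, None]) ** 2),
        "Id": np.einsum("dij,ij->d", p, 1.0 / (1.0 + np.abs(I - J))),
        "Idm": np.einsum("dij,ij->d", p, 1.0 / (1.0 + (I - J) ** 2)),
        "Idmn": np.einsum("dij,ij->d", p, 1.0 / (1.0 + ((I - J) ** 2) / ng**2)),
        "Idn": np.einsum("dij,ij->d", p, 1.0 / (1.0 + np.abs(I - J) / ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": (p**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MaximumProbability": p.max(axis=(1, 2)),
        "MCC": mcc,
        "SumAverage": (p_sum * k_sum).sum(axis=1),
        "SumEntropy": -_xlog2(p_sum).sum(axis=1),
        "SumSquares": np.einsum("dij,dij->d", p,
                                (I[None] - ux[:, None, None]) ** 2),
    }
    return {name: float(vals[name].mean()) for name in _GLCM_NAMES}


def gldm_features(P: np.ndarray) -> dict:
    """14 gray-level dependence features."""
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / nz
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((pi * i[:, 0]).sum())
    mu_j = float((pj * j[0]).sum())
    pd = p[p > 0]
    return {
        "DependenceEntropy": float(-np.sum(pd * np.log2(pd))),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "DependenceVariance": float((pj * (j[0] - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelVariance": float((pi * (i[:, 0] - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nz),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "SmallDependenceEmphasis": float((P / j**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nz),
    }


_GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def _single_glrlm_features(P: np.ndarray, n_voxels: int) -> dict:
    nr = P.sum()
    if nr == 0:
        return {k: 0.0 for k in _GLRLM_NAMES}
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / nr
    pi = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float((pi * i[:, 0]).sum())
    mu_l = float((pl * l[0]).sum())
    pd = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / nr**2),
        "GrayLevelVariance": float((pi * (i[:, 0] - mu_i) ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "LongRunEmphasis": float((P * l**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * l**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * l**2 / i**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "RunEntropy": float(-np.sum(pd * np.log2(pd))),
        "RunLengthNonUniformity": float((P.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float((pl * (l[0] - mu_l) ** 2).sum()),
        "ShortRunEmphasis": float((P / l**2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / l**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * l**2)).sum() / nr),
    }


def glrlm_features(mats: np.ndarray, n_voxels: int) -> dict:
    """16 run-length features, averaged over the 13 directions."""
    per_dir = [_single_glrlm_features(mats[d], n_voxels)
               for d in range(mats.shape[0])]
    return {name: float(np.mean([f[name] for f in per_dir]))
            for name in _GLRLM_NAMES}


def glszm_features(P: np.ndarray, n_voxels: int) -> dict:
    """16 size-zone features."""
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / nz
    pi = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((pi * i[:, 0]).sum())
    mu_s = float((ps * s[0]).sum())
    pd = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / nz**2),
        "GrayLevelVariance": float((pi * (i[:, 0] - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "SizeZoneNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "ZoneEntropy": float(-np.sum(pd * np.log2(pd))),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float((ps * (s[0] - mu_s) ** 2).sum()),
    }


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict:
    """5 neighboring gray-tone difference features."""
    N = n.sum()
    present = n > 0
    ngp = int(present.sum())
    p = n / N
    i = np.arange(1, len(n) + 1, dtype=float)
    ip = i[present]
    pp = p[present]
    sp = s[present]

    coarse_den = float((pp * sp).sum())
    coarseness = min(1.0 / coarse_den, 1e6) if coarse_den > 0 else 1e6

    if ngp > 1:
        diff2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = (float((pp[:, None] * pp[None, :] * diff2).sum())
                    / (ngp * (ngp - 1))) * float(s.sum() / N)
        busy_den = float(np.abs(ip[:, None] * pp[:, None]
                                - ip[None, :] * pp[None, :]).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        absdiff = np.abs(ip[:, None] - ip[None, :])
        pair_sum = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        complexity = float((absdiff * pair_sum
                            / (pp[:, None] + pp[None, :])).sum()) / N
        s_total = float(s.sum())
        strength = (float(((pp[:, None] + pp[None, :]) * diff2).sum())
                    / s_total) if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def texture_features(levels: np.ndarray, ng: int) -> dict:
    """All 75 texture features of a discretized region.

    Returns an ordered dict keyed ``<family>_<Feature>`` with families
    glcm (24), gldm (14), glrlm (16), glszm (16) and ngtdm (5).
    """
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty region")
    out: dict[str, float] = {}
    for name, val in glcm_features(glcm_matrices(levels, ng)).items():
        out[f"glcm_{name}"] = val
    for name, val in gldm_features(gldm_matrix(levels, ng)).items():
        out[f"gldm_{name}"] = val
    for name, val in glrlm_features(glrlm_matrices(levels, ng), n_voxels).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(glszm_matrix(levels, ng), n_voxels).items():
        out[f"glszm_{name}"] = val
    for name, val in ngtdm_features(*ngtdm_table(levels, ng)).items():
        out[f"ngtdm_{name}"] = val
    return out
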