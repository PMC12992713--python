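"""Gray-level texture matrices and their feature sets.

Five families over a discretized ROI (integer levels 1..Ng on a 3D grid,
0 marking out-of-ROI voxels):

* GLCM  — symmetric co-occurrence counts at distance 1 over the 13 unique
  3D directions; 24 features, averaged over directions.
* GLRLM — run-length counts per direction; 16 features, direction-averaged.
* GLSZM — 26-connected same-level zone sizes; 16 features.
* GLDM  — dependence counts (center voxel plus 26-neighbors within a level
  difference of α, default 0); 14 features.
* NGTDM — per-level counts and sums of |level − mean of valid neighbors|;
  5 features.

All matrices are restricted to in-ROI voxels; feature definitions follow
the standard radiomics reference set with probability normalization first.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "texture_matrix",
    "texture_features",
    "TEXTURE_FAMILIES",
    "TEXTURE_FEATURE_NAMES",
]

#: the 13 unique distance-1 direction vectors of a 3D lattice (up to sign)
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")


def _shift(a: np.ndarray, d: tuple[int, ...]) -> np.ndarray:
    """out[i] = a[i + d], zero-filled at the borders."""
    out = np.zeros_like(a)
    src, dst = [], []
    for n, di in zip(a.shape, d):
        if di >= 0:
            dst.append(slice(0, n - di))
            src.append(slice(di, n))
        else:
            dst.append(slice(-di, n))
            src.append(slice(0, n + di))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# matrices


def _glcm(lv: np.ndarray, ng: int) -> np.ndarray:
    """(13, Ng, Ng) symmetric co-occurrence counts."""
    out = np.zeros((len(DIRECTIONS_13), ng, ng))
    for di, d in enumerate(DIRECTIONS_13):
        nb = _shift(lv, d)
        ok = (lv > 0) & (nb > 0)
        pairs = (lv[ok] - 1) * ng + (nb[ok] - 1)
        m = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng).astype(float)
        out[di] = m + m.T
    return out


def _glrlm(lv: np.ndarray, ng: int) -> np.ndarray:
    """(13, Ng, Lmax) run-length counts via a per-direction sweep DP."""
    valid = lv > 0
    per_dir = []
    lmax = 1
    for d in DIRECTIONS_13:
        k = next(i for i, v in enumerate(d) if v != 0)  # d[k] == +1 by table
        lvk = np.moveaxis(lv, k, 0)
        vk = np.moveaxis(valid, k, 0)
        rest = tuple(-d[i] for i in range(3) if i != k)
        g = np.zeros(lvk.shape, dtype=int)
        for t in range(lvk.shape[0]):
            if t == 0:
                g[t] = vk[t].astype(int)
            else:
                prev_lv = _shift(lvk[t - 1], rest)
                prev_g = _shift(g[t - 1], rest)
                cont = vk[t] & (prev_lv == lvk[t])
                g[t] = np.where(cont, prev_g + 1, vk[t].astype(int))
        g_full = np.moveaxis(g, 0, k)
        nxt = _shift(lv, d)
        run_end = valid & ~((nxt > 0) & (nxt == lv))
        levels = lv[run_end] - 1
        lengths = g_full[run_end]
        lmax = max(lmax, int(lengths.max()) if lengths.size else 1)
        per_dir.append((levels, lengths))
    out = np.zeros((len(DIRECTIONS_13), ng, lmax))
    for di, (levels, lengths) in enumerate(per_dir):
        np.add.at(out[di], (levels, lengths - 1), 1.0)
    return out


def _glszm(lv: np.ndarray, ng: int) -> np.ndarray:
    """(Ng, Smax) zone-size counts; zones are 26-connected same-level sets."""
    zones: list[tuple[int, int]] = []
    smax = 1
    for g in range(1, ng + 1):
        comp, ncomp = ndimage.label(lv == g, structure=_STRUCT_26)
        if ncomp:
            sizes = np.bincount(comp.ravel())[1:]
            smax = max(smax, int(sizes.max()))
            zones.extend((g, int(s)) for s in sizes)
    out = np.zeros((ng, smax))
    for g, s in zones:
        out[g - 1, s - 1] += 1.0
    return out


def _gldm(lv: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """(Ng, Dmax) dependence counts; dependence size counts the center voxel
    plus every 26-neighbor whose level differs by at most alpha."""
    valid = lv > 0
    dep = np.ones(lv.shape, dtype=int)  # the center is dependent on itself
    for d in _OFFSETS_26:
        nb = _shift(lv, d)
        dep += (valid & (nb > 0) & (np.abs(nb - lv) <= alpha)).astype(int)
    levels = lv[valid] - 1
    sizes = dep[valid]
    out = np.zeros((ng, int(sizes.max())))
    np.add.at(out, (levels, sizes - 1), 1.0)
    return out


def _ngtdm(lv: np.ndarray, ng: int) -> np.ndarray:
    """(Ng, 2): per level, the voxel count n_i and the sum s_i of absolute
    differences to the mean of the valid 26-neighborhood."""
    valid = lv > 0
    nb_sum = np.zeros(lv.shape)
    nb_cnt = np.zeros(lv.shape)
    for d in _OFFSETS_26:
        nb = _shift(lv, d)
        ok = nb > 0
        nb_sum += np.where(ok, nb, 0)
        nb_cnt += ok
    use = valid & (nb_cnt > 0)
    diff = np.zeros(lv.shape)
    diff[use] = np.abs(lv[use] - nb_sum[use] / nb_cnt[use])
    out = np.zeros((ng, 2))
    for g in range(1, ng + 1):
        sel = use & (lv == g)
        out[g - 1, 0] = sel.sum()
        out[g - 1, 1] = diff[sel].sum()
    return out


def texture_matrix(family: str, lv: np.ndarray, ng: int, **params) -> np.ndarray:
    """Compute one texture matrix family on a labeled-level grid.

    ``lv`` holds integer gray levels 1..``ng`` with 0 outside the ROI.
    GLCM/GLRLM return a stack over the 13 directions.
    """
    lv = np.asarray(lv, dtype=int)
    if ng < 1:
        raise ValueError("need at least one gray level")
    if not (lv > 0).any():
        raise ValueError("empty ROI")
    fam = family.lower()
    if fam == "glcm":
        return _glcm(lv, ng)
    if fam == "glrlm":
        return _glrlm(lv, ng)
    if fam == "glszm":
        return _glszm(lv, ng)
    if fam == "gldm":
        return _gldm(lv, ng, int(params.get("alpha", 0)))
    if fam == "ngtdm":
        return _ngtdm(lv, ng)
    raise ValueError(f"unknown texture family {family!r}")


# ---------------------------------------------------------------------------
# features

_EPS = np.finfo(float).tiny


def _glcm_features(stack: np.ndarray) -> dict[str, float]:
    d, ng, _ = stack.shape
    sums = stack.sum(axis=(1, 2), keepdims=True)
    sums[sums == 0] = 1.0
    p = stack / sums
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[None, :, None]
    jj = i[None, None, :]
    px = p.sum(axis=2)  # (d, ng); symmetric => py == px
    ux = (px * i).sum(axis=1)  # (d,)
    sigx2 = (px * (i[None, :] - ux[:, None]) ** 2).sum(axis=1)

    kplus = (np.add.outer(i, i)).astype(int)  # 2..2Ng
    kminus = np.abs(np.subtract.outer(i, i)).astype(int)  # 0..Ng-1
    pplus = np.zeros((d, 2 * ng + 1))
    pminus = np.zeros((d, ng))
    for t in range(d):
        pplus[t] = np.bincount(kplus.ravel(), weights=p[t].ravel(), minlength=2 * ng + 1)
        pminus[t] = np.bincount(kminus.ravel(), weights=p[t].ravel(), minlength=ng)
    kp = np.arange(2 * ng + 1, dtype=float)
    km = np.arange(ng, dtype=float)

    autoc = (p * ii * jj).sum(axis=(1, 2))
    clus = ii + jj - 2 * ux[:, None, None]
    contrast = (p * (ii - jj) ** 2).sum(axis=(1, 2))
    corr = np.where(
        sigx2 > 0, (autoc - ux**2) / np.where(sigx2 > 0, sigx2, 1.0), 1.0
    )
    da = (pminus * km).sum(axis=1)
    dent = -(pminus * np.log2(pminus + _EPS) * (pminus > 0)).sum(axis=1)
    dvar = (pminus * (km[None, :] - da[:, None]) ** 2).sum(axis=1)
    jener = (p**2).sum(axis=(1, 2))
    jent = -(p * np.log2(p + _EPS) * (p > 0)).sum(axis=(1, 2))

    hx = -(px * np.log2(px + _EPS) * (px > 0)).sum(axis=1)
    pxy_ind = px[:, :, None] * px[:, None, :]
    hxy1 = -(p * np.log2(pxy_ind + _EPS) * (p > 0)).sum(axis=(1, 2))
    hxy2 = -(pxy_ind * np.log2(pxy_ind + _EPS) * (pxy_ind > 0)).sum(axis=(1, 2))
    denom = np.maximum(hx, _EPS)
    imc1 = np.where(hx > 0, (jent - hxy1) / denom, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - jent)), 0.0, None))

    absdiff = np.abs(ii - jj)
    idf = (p / (1.0 + absdiff)).sum(axis=(1, 2))
    idm = (p / (1.0 + absdiff**2)).sum(axis=(1, 2))
    idmn = (p / (1.0 + (absdiff / ng) ** 2)).sum(axis=(1, 2))
    idn = (p / (1.0 + absdiff / ng)).sum(axis=(1, 2))
    off = absdiff > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        invv = np.where(off, p / np.where(off, absdiff**2, 1.0), 0.0).sum(axis=(1, 2))
    maxp = p.max(axis=(1, 2))
    savg = (pplus * kp).sum(axis=1)
    sent = -(pplus * np.log2(pplus + _EPS) * (pplus > 0)).sum(axis=1)
    ssq = (p * (ii - ux[:, None, None]) ** 2).sum(axis=(1, 2))

    mcc = np.empty(d)
    for t in range(d):
        present = px[t] > 0
        if present.sum() < 2:
            mcc[t] = 1.0
            continue
        psub = p[t][np.ix_(present, present)]
        pxs = px[t][present]
        q = np.einsum("ik,jk->ij", psub, psub / pxs[None, :]) / pxs[:, None]
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc[t] = np.sqrt(max(ev[-2], 0.0)) if ev.size > 1 else 1.0

    feats = {
        "Autocorrelation": autoc,
        "ClusterProminence": (p * clus**4).sum(axis=(1, 2)),
        "ClusterShade": (p * clus**3).sum(axis=(1, 2)),
        "ClusterTendency": (p * clus**2).sum(axis=(1, 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": dent,
        "DifferenceVariance": dvar,
        "Id": idf,
        "Idm": idm,
        "Idmn": idmn,
        "Idn": idn,
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": invv,
        "JointAverage": ux,
        "JointEnergy": jener,
        "JointEntropy": jent,
        "MCC": mcc,
        "MaximumProbability": maxp,
        "SumAverage": savg,
        "SumEntropy": sent,
        "SumSquares": ssq,
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


def _run_zone_features(P: np.ndarray, nvox: int, kind: str) -> dict[str, float]:
    """Shared run-length / size-zone / dependence feature machinery.

    ``P`` is (D, Ng, L) for directional families or (1, Ng, L); features are
    averaged over the leading axis.
    """
    d, ng, lmax = P.shape
    i = np.arange(1, ng + 1, dtype=float)[None, :, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, None, :]
    nr = P.sum(axis=(1, 2))
    nr_safe = np.where(nr == 0, 1.0, nr)
    p = P / nr_safe[:, None, None]

    pg = P.sum(axis=2)  # (d, ng)
    pl = P.sum(axis=1)  # (d, lmax)
    mu_i = (p * i).sum(axis=(1, 2))
    mu_j = (p * j).sum(axis=(1, 2))

    feats = {
        "ShortEmphasis": (P / j**2).sum(axis=(1, 2)) / nr_safe,
        "LongEmphasis": (P * j**2).sum(axis=(1, 2)) / nr_safe,
        "GrayLevelNonUniformity": (pg**2).sum(axis=1) / nr_safe,
        "GrayLevelNonUniformityNormalized": (pg**2).sum(axis=1) / nr_safe**2,
        "SizeNonUniformity": (pl**2).sum(axis=1) / nr_safe,
        "SizeNonUniformityNormalized": (pl**2).sum(axis=1) / nr_safe**2,
        "Percentage": nr / max(nvox, 1),
        "GrayLevelVariance": (p * (i - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        "SizeVariance": (p * (j - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        "Entropy": -(p * np.log2(p + _EPS) * (p > 0)).sum(axis=(1, 2)),
        "LowGrayLevelEmphasis": (P / i**2).sum(axis=(1, 2)) / nr_safe,
        "HighGrayLevelEmphasis": (P * i**2).sum(axis=(1, 2)) / nr_safe,
        "ShortLowGrayLevelEmphasis": (P / (i**2 * j**2)).sum(axis=(1, 2)) / nr_safe,
        "ShortHighGrayLevelEmphasis": (P * i**2 / j**2).sum(axis=(1, 2)) / nr_safe,
        "LongLowGrayLevelEmphasis": (P * j**2 / i**2).sum(axis=(1, 2)) / nr_safe,
        "LongHighGrayLevelEmphasis": (P * i**2 * j**2).sum(axis=(1, 2)) / nr_safe,
    }
    out = {k: float(np.mean(v)) for k, v in feats.items()}

    if kind == "glrlm":
        ren = {
            "ShortEmphasis": "ShortRunEmphasis",
            "LongEmphasis": "LongRunEmphasis",
            "SizeNonUniformity": "RunLengthNonUniformity",
            "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
            "Percentage": "RunPercentage",
            "SizeVariance": "RunVariance",
            "Entropy": "RunEntropy",
            "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
            "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
            "ShortLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
            "ShortHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
            "LongLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
            "LongHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
        }
    elif kind == "glszm":
        ren = {
            "ShortEmphasis": "SmallAreaEmphasis",
            "LongEmphasis": "LargeAreaEmphasis",
            "SizeNonUniformity": "SizeZoneNonUniformity",
            "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
            "Percentage": "ZonePercentage",
            "SizeVariance": "ZoneVariance",
            "Entropy": "ZoneEntropy",
            "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
            "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
            "ShortLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
            "ShortHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
            "LongLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
            "LongHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
        }
    else:  # gldm
        ren = {
            "ShortEmphasis": "SmallDependenceEmphasis",
            "LongEmphasis": "LargeDependenceEmphasis",
            "SizeNonUniformity": "DependenceNonUniformity",
            "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
            "SizeVariance": "DependenceVariance",
            "Entropy": "DependenceEntropy",
            "ShortLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
            "ShortHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
            "LongLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
            "LongHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
        }
        # GLDM defines neither a normalized-GLN nor a percentage feature
        out.pop("GrayLevelNonUniformityNormalized")
        out.pop("Percentage")
    return {ren.get(k, k): v for k, v in out.items()}


def _ngtdm_features(m: np.ndarray) -> dict[str, float]:
    n_i = m[:, 0]
    s_i = m[:, 1]
    nvp = n_i.sum()
    if nvp == 0:
        return {k: float("nan") for k in TEXTURE_FEATURE_NAMES["ngtdm"]}
    p_i = n_i / nvp
    present = p_i > 0
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    ngp = int(present.sum())

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii_, jj_ = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = (
            (pi_ * pj_ * (ii_ - jj_) ** 2).sum() / (ngp * (ngp - 1))
        ) * (s_i.sum() / nvp)
        busy_den = np.abs(ii_ * pi_ - jj_ * pj_).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = (
            np.abs(ii_ - jj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)
        ).sum() / nvp
        strength_num = ((pi_ + pj_) * (ii_ - jj_) ** 2).sum()
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


def texture_features(family: str, matrix: np.ndarray, nvox: int | None = None) -> dict[str, float]:
    """Named features from one texture matrix (stack).

    ``nvox`` (ROI voxel count) is required for the percentage-type features
    of GLRLM and GLSZM.
    """
    fam = family.lower()
    if fam == "glcm":
        return _glcm_features(np.asarray(matrix, float))
    if fam == "glrlm":
        P = np.asarray(matrix, float)
        if nvox is None:
            j = np.arange(1, P.shape[-1] + 1, dtype=float)
            nvox = int(round((P[0] * j[None, :]).sum()))
        return _run_zone_features(P, nvox, "glrlm")
    if fam == "glszm":
        P = np.asarray(matrix, float)[None, :, :]
        if nvox is None:
            j = np.arange(1, P.shape[-1] + 1, dtype=float)
            nvox = int(round((P[0] * j[None, :]).sum()))
        return _run_zone_features(P, nvox, "glszm")
    if fam == "gldm":
        P = np.asarray(matrix, float)[None, :, :]
        return _run_zone_features(P, int(P.sum()), "gldm")
    if fam == "ngtdm":
        return _ngtdm_features(np.asarray(matrix, float))
    raise ValueError(f"unknown texture family {family!r}")


TEXTURE_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
        "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "glrlm": (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
        "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis",
    ),
    "glszm": (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
        "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
    ),
    "gldm": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
}
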