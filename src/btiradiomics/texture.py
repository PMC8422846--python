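"""Gray-level texture matrices and their derived features.

Implements the five standardized texture families used in interface
radiomics — co-occurrence (GLCM), run length (GLRLM), size zone (GLSZM),
neighborhood gray-tone difference (NGTDM) and dependence (GLDM) — on a
discretized 3D ROI.  Conventions:

* input is an integer level volume (levels >= 1 inside the ROI) plus a
  boolean ROI mask; voxels outside the mask never contribute;
* GLCM and GLRLM aggregate counts over the 13 unique 3D offsets at
  Chebyshev distance 1, summed before normalization; the GLCM is
  symmetrized;
* GLSZM zones and GLDM/NGTDM neighborhoods use 26-connectivity;
* GLDM dependence of a voxel is 1 (the center) plus the number of in-mask
  26-neighbors whose level differs by at most ``alpha`` (default 0);
* logarithms are base 2; empty rows/columns of a matrix are dropped before
  feature computation, and degenerate single-level ROIs yield finite,
  documented values rather than NaN.

Feature lists match the class sizes of the interface-radiomics study
configuration: GLCM 21, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "OFFSETS_13",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_table",
    "gldm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "texture_features",
    "TEXTURE_CLASSES",
]

_EPS = np.finfo(np.float64).eps

#: The 13 unique 3D direction offsets at Chebyshev distance 1.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)


def _check(levels: np.ndarray, mask: np.ndarray) -> int:
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    if levels.shape != mask.shape or levels.ndim != 3:
        raise ValueError("levels and mask must be aligned 3D arrays")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if (levels[mask] < 1).any():
        raise ValueError("levels inside the ROI must be >= 1")
    return int(levels[mask].max())


def _shift_pairs(arr: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """In-mask (center, neighbor) index pairs for one offset."""
    sl_a, sl_b = [], []
    for o in off:
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(None, -o))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return arr[sl_a][valid], arr[sl_b][valid]


# ---------------------------------------------------------------------------
# matrices


def glcm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric co-occurrence counts summed over the 13 offsets.

    Returns an (Ng, Ng) count matrix over levels 1..Ng (Ng = max level in
    the ROI); normalize by its sum for joint probabilities.
    """
    ng = _check(levels, mask)
    mask = np.asarray(mask, bool)
    counts = np.zeros(ng * ng, dtype=np.int64)
    for off in OFFSETS_13:
        a, b = _shift_pairs(levels, mask, off)
        if len(a):
            counts += np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng)
    counts = counts.reshape(ng, ng)
    return counts + counts.T


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Run-length counts R(level, run length) summed over the 13 directions."""
    ng = _check(levels, mask)
    mask = np.asarray(mask, bool)
    coords = np.argwhere(mask)
    lev = levels[mask]
    n = coords.shape[0]
    counts: dict[tuple[int, int], int] = {}
    for off in OFFSETS_13:
        d = np.asarray(off)
        # line key: project out the direction component
        first = int(np.nonzero(d)[0][0])
        s = coords[:, first] * d[first]  # position along the line (d[first] is +-1)
        key = coords - s[:, None] * d[None, :]
        order = np.lexsort((s, key[:, 2], key[:, 1], key[:, 0]))
        ks, ss, ls = key[order], s[order], lev[order]
        same_line = np.all(ks[1:] == ks[:-1], axis=1) & (ss[1:] == ss[:-1] + 1)
        run_breaks = ~(same_line & (ls[1:] == ls[:-1]))
        starts = np.concatenate([[0], np.nonzero(run_breaks)[0] + 1])
        ends = np.concatenate([np.nonzero(run_breaks)[0], [n - 1]])
        lengths = ends - starts + 1
        run_levels = ls[starts]
        for gl, rl in zip(run_levels, lengths):
            counts[(int(gl), int(rl))] = counts.get((int(gl), int(rl)), 0) + 1
    max_rl = max(rl for _, rl in counts)
    R = np.zeros((ng, max_rl), dtype=np.int64)
    for (gl, rl), c in counts.items():
        R[gl - 1, rl - 1] = c
    return R


def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size-zone counts S(level, zone size); zones are 26-connected."""
    ng = _check(levels, mask)
    mask = np.asarray(mask, bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for gl in np.unique(levels[mask]):
        lab, nlab = ndimage.label((levels == gl) & mask, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            counts[(int(gl), int(sz))] = counts.get((int(gl), int(sz)), 0) + 1
    max_sz = max(sz for _, sz in counts)
    S = np.zeros((ng, max_sz), dtype=np.int64)
    for (gl, sz), c in counts.items():
        S[gl - 1, sz - 1] = c
    return S


def _neighbor_sum_count(values: np.ndarray, mask: np.ndarray):
    """Sum and count of in-mask 26-neighbors for every voxel."""
    vals = np.where(mask, values.astype(np.float64), 0.0)
    cnt = mask.astype(np.float64)
    k = np.ones((3, 3, 3))
    k[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(vals, k, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(cnt, k, mode="constant", cval=0.0)
    return nb_sum, np.rint(nb_cnt).astype(np.int64)


def ngtdm_table(levels: np.ndarray, mask: np.ndarray):
    """Per-level occurrence counts ``n_i`` and summed tone differences ``s_i``.

    ``s_i`` sums, over voxels of level i that have at least one in-mask
    neighbor, the absolute difference between i and the mean level of the
    in-mask 26-neighborhood.
    """
    ng = _check(levels, mask)
    mask = np.asarray(mask, bool)
    nb_sum, nb_cnt = _neighbor_sum_count(levels, mask)
    has_nb = mask & (nb_cnt > 0)
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=np.float64)
    lv = levels[has_nb]
    diffs = np.abs(lv - nb_sum[has_nb] / nb_cnt[has_nb])
    np.add.at(n, lv - 1, 1)
    np.add.at(s, lv - 1, diffs)
    return n, s


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(level, dependence size).

    Dependence size of a voxel = 1 + number of in-mask 26-neighbors whose
    level differs from the center by at most ``alpha``.
    """
    ng = _check(levels, mask)
    mask = np.asarray(mask, bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        sl_a, sl_b = [], []
        for c in off:
            if c == 0:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
            elif c > 0:
                sl_a.append(slice(None, -c))
                sl_b.append(slice(c, None))
            else:
                sl_a.append(slice(-c, None))
                sl_b.append(slice(None, c))
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        ok = (
            mask[sl_a]
            & mask[sl_b]
            & (np.abs(levels[sl_a].astype(np.int64) - levels[sl_b]) <= alpha)
        )
        dep[sl_a] += ok
        dep[sl_b] += ok
    dep_in = dep[mask] + 1
    lev_in = levels[mask]
    nd = int(dep_in.max())
    flat = np.bincount((lev_in - 1) * nd + (dep_in - 1), minlength=ng * nd)
    return flat.reshape(ng, nd)


# ---------------------------------------------------------------------------
# features


def _trim(counts: np.ndarray):
    """Drop all-zero gray-level rows; return (matrix, level values, col values)."""
    rows = counts.sum(axis=1) > 0
    cols = counts.sum(axis=0) > 0
    i_vals = np.nonzero(rows)[0] + 1.0
    j_vals = np.nonzero(cols)[0] + 1.0
    return counts[np.ix_(rows, cols)].astype(np.float64), i_vals, j_vals


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 21 co-occurrence features of the study configuration."""
    # GLCM is square/symmetric: keep matching rows and columns
    rows = counts.sum(axis=1) > 0
    P = counts[np.ix_(rows, rows)].astype(np.float64)
    iv = np.nonzero(rows)[0] + 1.0
    p = P / P.sum()
    ng = len(iv)
    i = iv[:, None]
    j = iv[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * iv).sum())
    mu_y = float((py * iv).sum())
    sig_x = float(np.sqrt((px * (iv - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (iv - mu_y) ** 2).sum()))
    # diagonal (difference) and cross-diagonal (sum) distributions
    ii = iv.astype(np.int64)
    kdiff = np.abs(ii[:, None] - ii[None, :])
    ksum = ii[:, None] + ii[None, :]
    d_vals = np.arange(0, int(iv[-1] - iv[0]) + 1, dtype=np.float64)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(),
                         minlength=len(d_vals))[: len(d_vals)]
    lo = int(2 * iv[0])
    s_vals = np.arange(lo, int(2 * iv[-1]) + 1, dtype=np.float64)
    p_sum = np.bincount(ksum.ravel() - lo, weights=p.ravel(),
                        minlength=len(s_vals))[: len(s_vals)]

    def ent(x):
        x = x[x > 0]
        return float(-(x * np.log2(x)).sum())

    da = float((d_vals * p_diff).sum())
    hxy = ent(p.ravel())
    pxy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.log2(pxy + _EPS)).sum())
    hxy2 = ent(pxy.ravel())
    hx, hy = ent(px), ent(py)
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    if sig_x * sig_y > 0:
        corr = float(((p * i * j).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        corr = 1.0
    nz = d_vals > 0
    feats = {
        "Autocorrelation": float((p * i * j).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((p * (i + j - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((p * (i + j - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((d_vals - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p_diff / (1.0 + d_vals**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (d_vals / ng) ** 2)).sum()),
        "Id": float((p_diff / (1.0 + d_vals)).sum()),
        "Idn": float((p_diff / (1.0 + d_vals / ng)).sum()),
        "InverseVariance": float((p_diff[nz] / d_vals[nz] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
    }
    return feats


def _sz_family(counts: np.ndarray, prefix_small: str, prefix_large: str,
               names: dict[str, str], n_voxels: int) -> dict[str, float]:
    """Shared feature algebra of GLRLM / GLSZM / GLDM (level x size matrices)."""
    M, iv, jv = _trim(counts)
    nz = M.sum()
    p = M / nz
    i = iv[:, None]
    j = jv[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pn = p[p > 0]
    feats = {
        prefix_small: float((p / j**2).sum()),
        prefix_large: float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((M.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        names["size_nu"]: float((M.sum(axis=0) ** 2).sum() / nz),
        names["size_nu_norm"]: float((ps**2).sum()),
        names["percentage"]: float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        names["size_var"]: float((p * (j - mu_j) ** 2).sum()),
        names["entropy"]: float(-(pn * np.log2(pn)).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        names["small_low"]: float((p / (i**2 * j**2)).sum()),
        names["small_high"]: float((p * i**2 / j**2).sum()),
        names["large_low"]: float((p * j**2 / i**2).sum()),
        names["large_high"]: float((p * i**2 * j**2).sum()),
    }
    return feats


def glrlm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 run-length features; ``n_voxels`` is the ROI size (runs are
    counted over 13 directions, so run percentage uses ``13 * n_voxels``)."""
    f = _sz_family(
        counts,
        "ShortRunEmphasis",
        "LongRunEmphasis",
        {
            "size_nu": "RunLengthNonUniformity",
            "size_nu_norm": "RunLengthNonUniformityNormalized",
            "percentage": "RunPercentage",
            "size_var": "RunVariance",
            "entropy": "RunEntropy",
            "small_low": "ShortRunLowGrayLevelEmphasis",
            "small_high": "ShortRunHighGrayLevelEmphasis",
            "large_low": "LongRunLowGrayLevelEmphasis",
            "large_high": "LongRunHighGrayLevelEmphasis",
        },
        13 * n_voxels,
    )
    f["LowGrayLevelRunEmphasis"] = f.pop("LowGrayLevelEmphasis")
    f["HighGrayLevelRunEmphasis"] = f.pop("HighGrayLevelEmphasis")
    return f


def glszm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 size-zone features."""
    f = _sz_family(
        counts,
        "SmallAreaEmphasis",
        "LargeAreaEmphasis",
        {
            "size_nu": "SizeZoneNonUniformity",
            "size_nu_norm": "SizeZoneNonUniformityNormalized",
            "percentage": "ZonePercentage",
            "size_var": "ZoneVariance",
            "entropy": "ZoneEntropy",
            "small_low": "SmallAreaLowGrayLevelEmphasis",
            "small_high": "SmallAreaHighGrayLevelEmphasis",
            "large_low": "LargeAreaLowGrayLevelEmphasis",
            "large_high": "LargeAreaHighGrayLevelEmphasis",
        },
        n_voxels,
    )
    f["LowGrayLevelZoneEmphasis"] = f.pop("LowGrayLevelEmphasis")
    f["HighGrayLevelZoneEmphasis"] = f.pop("HighGrayLevelEmphasis")
    return f


def gldm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 14 dependence features."""
    f = _sz_family(
        counts,
        "SmallDependenceEmphasis",
        "LargeDependenceEmphasis",
        {
            "size_nu": "DependenceNonUniformity",
            "size_nu_norm": "DependenceNonUniformityNormalized",
            "percentage": "_drop_percentage",
            "size_var": "DependenceVariance",
            "entropy": "DependenceEntropy",
            "small_low": "SmallDependenceLowGrayLevelEmphasis",
            "small_high": "SmallDependenceHighGrayLevelEmphasis",
            "large_low": "LargeDependenceLowGrayLevelEmphasis",
            "large_high": "LargeDependenceHighGrayLevelEmphasis",
        },
        n_voxels,
    )
    # every voxel has exactly one dependence entry, so a percentage and the
    # normalized gray-level non-uniformity are dropped from this family
    f.pop("_drop_percentage")
    f.pop("GrayLevelNonUniformityNormalized")
    return f


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features."""
    np_tot = int(n.sum())
    iv = np.arange(1, len(n) + 1, dtype=np.float64)
    present = n > 0
    pi = n / np_tot
    ngp = int(present.sum())
    i = iv[present]
    p = pi[present]
    si = s[present]
    coars_den = float((p * si).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6
    if ngp > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(
            (p[:, None] * p[None, :] * dij2).sum() / (ngp * (ngp - 1)) * si.sum() / np_tot
        )
        busy_den = float(np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :]).sum())
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        pij = p[:, None] + p[None, :]
        complexity = float(
            (np.abs(i[:, None] - i[None, :]) * (p[:, None] * si[:, None] + p[None, :] * si[None, :]) / pij).sum()
            / np_tot
        )
        s_sum = float(si.sum())
        strength = float((pij * dij2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


TEXTURE_CLASSES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")


def texture_features(
    levels: np.ndarray,
    mask: np.ndarray,
    classes: tuple[str, ...] = TEXTURE_CLASSES,
    gldm_alpha: int = 0,
) -> dict[str, float]:
    """All requested texture-family features, keyed ``class_FeatureName``."""
    mask = np.asarray(mask, bool)
    # crop to the ROI bounding box: every family is mask-local
    nz = np.nonzero(mask)
    if len(nz[0]) == 0:
        raise ValueError("ROI mask is empty")
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    mask = mask[sl]
    levels = np.asarray(levels)[sl]
    nvox = int(mask.sum())
    out: dict[str, float] = {}
    for cls in classes:
        if cls == "glcm":
            feats = glcm_features(glcm_matrix(levels, mask))
        elif cls == "glrlm":
            feats = glrlm_features(glrlm_matrix(levels, mask), nvox)
        elif cls == "glszm":
            feats = glszm_features(glszm_matrix(levels, mask), nvox)
        elif cls == "ngtdm":
            feats = ngtdm_features(*ngtdm_table(levels, mask))
        elif cls == "gldm":
            feats = gldm_features(gldm_matrix(levels, mask, alpha=gldm_alpha), nvox)
        else:
            raise ValueError(f"unknown texture class {cls!r}")
        out.update({f"{cls}_{k}": v for k, v in feats.items()})
    return out
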