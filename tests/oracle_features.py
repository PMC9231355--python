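"""Brute-force reference implementation of the 93 dosiomic features.

Everything here is written as direct, naive summation over voxels and matrix
cells — explicit Python loops, BFS flood fill for zones, step-by-step line
walking for runs — so it can serve as an independent oracle for the
vectorized extractor on small images.  Conventions mirror the package's
documented choices (13-direction averaging, base-2 logs with zero terms
skipped, present-level count in normalised formulas, population moments).
"""

from __future__ import annotations

import math
from collections import defaultdict, deque

import numpy as np

DIRS_13 = []
for dx in (-1, 0, 1):
    for dy in (-1, 0, 1):
        for dz in (-1, 0, 1):
            if (dx, dy, dz) > (0, 0, 0):
                DIRS_13.append((dx, dy, dz))
assert len(DIRS_13) == 13
DIRS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def oracle_discretize(dose, mask, lo=0.0, hi=70.0, ng=70):
    shape = dose.shape
    levels = np.zeros(shape, dtype=int)
    w = (hi - lo) / ng
    for idx in np.ndindex(shape):
        if mask[idx]:
            lv = math.floor((dose[idx] - lo) / w) + 1
            levels[idx] = min(max(lv, 1), ng)
    return levels


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def _entropy2(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


# ----------------------------------------------------------------- matrices

def oracle_glcm(levels, mask, ng, direction):
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for sgn in (1, -1):
            nb = tuple(c + sgn * d for c, d in zip(idx, direction))
            if _inside(shape, nb) and mask[nb]:
                mat[levels[idx] - 1, levels[nb] - 1] += 1
    return mat


def oracle_glrlm(levels, mask, ng, direction):
    shape = levels.shape
    runs = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        prev = tuple(c - d for c, d in zip(idx, direction))
        if _inside(shape, prev) and mask[prev] and levels[prev] == levels[idx]:
            continue  # not the start of a run
        length = 1
        cur = idx
        while True:
            nxt = tuple(c + d for c, d in zip(cur, direction))
            if _inside(shape, nxt) and mask[nxt] and levels[nxt] == levels[idx]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[idx], length))
    if not runs:
        return np.zeros((ng, 1))
    max_len = max(l for _, l in runs)
    mat = np.zeros((ng, max_len))
    for lv, l in runs:
        mat[lv - 1, l - 1] += 1
    return mat


def oracle_glszm(levels, mask, ng):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        lv = levels[start]
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for d in DIRS_26:
                nb = tuple(c + dd for c, dd in zip(cur, d))
                if (_inside(shape, nb) and mask[nb] and not seen[nb]
                        and levels[nb] == lv):
                    seen[nb] = True
                    queue.append(nb)
        zones.append((lv, size))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for lv, s in zones:
        mat[lv - 1, s - 1] += 1
    return mat


def oracle_ngtdm(levels, mask, ng):
    shape = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb_levels = [
            levels[tuple(c + dd for c, dd in zip(idx, d))]
            for d in DIRS_26
            if _inside(shape, tuple(c + dd for c, dd in zip(idx, d)))
            and mask[tuple(c + dd for c, dd in zip(idx, d))]
        ]
        if not nb_levels:
            continue
        abar = sum(nb_levels) / len(nb_levels)
        s[levels[idx] - 1] += abs(levels[idx] - abar)
        n[levels[idx] - 1] += 1
    return s, n


def oracle_gldm(levels, mask, ng, alpha=0):
    shape = levels.shape
    entries = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        dep = 1
        for d in DIRS_26:
            nb = tuple(c + dd for c, dd in zip(idx, d))
            if (_inside(shape, nb) and mask[nb]
                    and abs(int(levels[nb]) - int(levels[idx])) <= alpha):
                dep += 1
        entries.append((levels[idx], dep))
    max_dep = max(d for _, d in entries)
    mat = np.zeros((ng, max_dep))
    for lv, d in entries:
        mat[lv - 1, d - 1] += 1
    return mat


# ----------------------------------------------------------------- features

def oracle_firstorder(dose, mask, levels, ng, voxel_volume):
    x = np.sort(dose[mask].astype(float))
    n = x.size
    mean = x.mean()
    var = float(np.mean((x - mean) ** 2))
    sd = math.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    counts = defaultdict(int)
    for lv in levels[mask]:
        counts[lv] += 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in x)
    robust = x[(x >= p10) & (x <= p90)]
    rmean = robust.mean()
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2
    else:
        skew = kurt = 0.0
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": _entropy2(probs),
        "Minimum": float(x[0]),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x[-1]),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x[-1] - x[0]),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - rmean))),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


def oracle_glcm_features(mat, ng_present):
    ng = mat.shape[0]
    total = mat.sum()
    p = mat / total
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    pxmy = [0.0] * ng
    pxpy = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            pxmy[abs(i - j)] += p[i, j]
            pxpy[i + j + 2] += p[i, j]
    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    da = sum(k * pxmy[k] for k in range(ng))
    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    hxy2 = _entropy2([px[i] * px[j] for i in range(ng) for j in range(ng)])
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) > 1:
        m = len(present)
        q = np.zeros((m, m))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * px[k]) for k in present
                )
        eig = sorted(abs(v) for v in np.linalg.eigvals(q))
        mcc = math.sqrt(max(0.0, eig[-2].real if hasattr(eig[-2], "real") else eig[-2]))
    else:
        mcc = 1.0
    feats = {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + j + 2 - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum(
            (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "Correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 1e-14 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(pxmy),
        "DifferenceVariance": sum((k - da) ** 2 * pxmy[k] for k in range(ng)),
        "JointEnergy": sum(v * v for v in p.ravel()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(pxmy[k] / (1 + k * k) for k in range(ng)),
        "Idmn": sum(pxmy[k] / (1 + (k / ng_present) ** 2) for k in range(ng)),
        "Id": sum(pxmy[k] / (1 + k) for k in range(ng)),
        "Idn": sum(pxmy[k] / (1 + k / ng_present) for k in range(ng)),
        "InverseVariance": sum(pxmy[k] / k**2 for k in range(1, ng)),
        "MaximumProbability": float(p.max()),
        "SumAverage": sum(k * pxpy[k] for k in range(2, 2 * ng + 1)),
        "SumEntropy": _entropy2(pxpy),
        "SumSquares": sigma2,
        "MCC": mcc,
    }
    return feats


def _oracle_sizes(mat, n_voxels, names):
    """Generic gray-level x size/length/dependence features by direct sums."""
    ng, mx = mat.shape
    ns = mat.sum()
    out = {}
    out["small"] = sum(mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(mx)) / ns
    out["large"] = sum(mat[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(mx)) / ns
    out["low"] = sum(mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(mx)) / ns
    out["high"] = sum(mat[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(mx)) / ns
    out["sl"] = sum(
        mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(mx)
    ) / ns
    out["sh"] = sum(
        mat[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(mx)
    ) / ns
    out["ll"] = sum(
        mat[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(mx)
    ) / ns
    out["lh"] = sum(
        mat[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(mx)
    ) / ns
    out["gln"] = sum(mat[i, :].sum() ** 2 for i in range(ng)) / ns
    out["glnn"] = out["gln"] / ns
    out["sn"] = sum(mat[:, j].sum() ** 2 for j in range(mx)) / ns
    out["snn"] = out["sn"] / ns
    out["pct"] = ns / n_voxels
    mu_i = sum((i + 1) * mat[i, :].sum() / ns for i in range(ng))
    mu_j = sum((j + 1) * mat[:, j].sum() / ns for j in range(mx))
    out["glv"] = sum(
        (i + 1 - mu_i) ** 2 * mat[i, :].sum() / ns for i in range(ng)
    )
    out["sv"] = sum(
        (j + 1 - mu_j) ** 2 * mat[:, j].sum() / ns for j in range(mx)
    )
    out["entropy"] = _entropy2((mat / ns).ravel())
    return {names[k]: out[k] for k in names}


GLRLM_MAP = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "low": "LowGrayLevelRunEmphasis", "high": "HighGrayLevelRunEmphasis",
    "sl": "ShortRunLowGrayLevelEmphasis", "sh": "ShortRunHighGrayLevelEmphasis",
    "ll": "LongRunLowGrayLevelEmphasis", "lh": "LongRunHighGrayLevelEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glv": "GrayLevelVariance", "sv": "RunVariance",
    "entropy": "RunEntropy",
}
GLSZM_MAP = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "low": "LowGrayLevelZoneEmphasis", "high": "HighGrayLevelZoneEmphasis",
    "sl": "SmallAreaLowGrayLevelEmphasis", "sh": "SmallAreaHighGrayLevelEmphasis",
    "ll": "LargeAreaLowGrayLevelEmphasis", "lh": "LargeAreaHighGrayLevelEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glv": "GrayLevelVariance", "sv": "ZoneVariance",
    "entropy": "ZoneEntropy",
}
GLDM_MAP = {
    "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
    "low": "LowGrayLevelEmphasis", "high": "HighGrayLevelEmphasis",
    "sl": "SmallDependenceLowGrayLevelEmphasis",
    "sh": "SmallDependenceHighGrayLevelEmphasis",
    "ll": "LargeDependenceLowGrayLevelEmphasis",
    "lh": "LargeDependenceHighGrayLevelEmphasis",
    "gln": "GrayLevelNonUniformity", "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "glv": "GrayLevelVariance", "sv": "DependenceVariance",
    "entropy": "DependenceEntropy",
}


def oracle_ngtdm_features(s, n):
    nvp = n.sum()
    ng = len(s)
    p = [ni / nvp for ni in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    coarse_denom = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in present for j in present
            ) / (ngp * (ngp - 1))
        ) * (sum(s) / nvp)
        busy_denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        s_sum = sum(s)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
        "Complexity": complexity, "Strength": strength,
    }


def oracle_all_features(dose, mask, lo=0.0, hi=70.0, ng=70, alpha=0,
                        voxel_volume=1.0):
    """All 93 features as {(class, name): value}; NaN for invalid classes."""
    dose = np.asarray(dose, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    levels = oracle_discretize(dose, mask, lo, hi, ng)
    n_voxels = int(mask.sum())
    ng_present = len({int(levels[idx]) for idx in np.ndindex(mask.shape) if mask[idx]})

    out = {}
    for k, v in oracle_firstorder(dose, mask, levels, ng, voxel_volume).items():
        out[("firstorder", k)] = v

    glcm_mats = [oracle_glcm(levels, mask, ng, d) for d in DIRS_13]
    glcm_mats = [m for m in glcm_mats if m.sum() > 0]
    if glcm_mats:
        per_dir = [oracle_glcm_features(m, ng_present) for m in glcm_mats]
        for name in per_dir[0]:
            out[("glcm", name)] = sum(f[name] for f in per_dir) / len(per_dir)
    else:
        for name in oracle_glcm_features(np.ones((2, 2)), 2):
            out[("glcm", name)] = float("nan")

    rl_mats = [oracle_glrlm(levels, mask, ng, d) for d in DIRS_13]
    rl_mats = [m for m in rl_mats if m.sum() > 0]
    per_dir = [_oracle_sizes(m, n_voxels, GLRLM_MAP) for m in rl_mats]
    for name in GLRLM_MAP.values():
        out[("glrlm", name)] = sum(f[name] for f in per_dir) / len(per_dir)

    for name, v in _oracle_sizes(oracle_glszm(levels, mask, ng), n_voxels,
                                 GLSZM_MAP).items():
        out[("glszm", name)] = v

    s, nn = oracle_ngtdm(levels, mask, ng)
    if nn.sum() > 0:
        for name, v in oracle_ngtdm_features(s, nn).items():
            out[("ngtdm", name)] = v
    else:
        for name in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"):
            out[("ngtdm", name)] = float("nan")

    for name, v in _oracle_sizes(oracle_gldm(levels, mask, ng, alpha), n_voxels,
                                 GLDM_MAP).items():
        out[("gldm", name)] = v
    return out
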