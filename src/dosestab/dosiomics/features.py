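"""The 93-feature dosiomic signature of one (dose grid, ROI mask) pair.

Feature classes and counts: 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
5 NGTDM, 14 GLDM.  Definitions follow the Image Biomarker Standardisation
Initiative conventions as realised by the widely used radiomics toolchain:

* first-order statistics are computed on the raw dose values in Gy, except
  Entropy and Uniformity which use the discretized gray-level histogram;
* GLCM and GLRLM features are computed per direction (13 directions,
  distance 1) and averaged; GLSZM/NGTDM/GLDM use a single aggregate matrix;
* logarithms are base 2 with zero-probability terms skipped;
* Skewness and Kurtosis use population (biased) moments and Kurtosis is not
  excess-corrected (a Gaussian scores 3);
* in formulas that normalise by the number of gray levels (Idmn, Idn,
  NGTDM Contrast) the count of levels actually present in the ROI is used.

Degenerate inputs (single-voxel ROI, empty co-occurrence counts, zero
variance) yield flagged-invalid or convention values rather than exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..grids import DoseGrid, RoiMask
from .discretize import DiscretizedRoi, discretize
from .matrices import TextureMatrices, build_texture_matrices

FIRSTORDER_NAMES = sorted([
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
])
GLCM_NAMES = sorted([
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
])
GLRLM_NAMES = sorted([
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
])
GLSZM_NAMES = sorted([
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
])
NGTDM_NAMES = sorted(["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"])
GLDM_NAMES = sorted([
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
])

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}
CANONICAL_ORDER: tuple[tuple[str, str], ...] = tuple(
    (cls, name) for cls in FEATURE_CLASSES for name in CLASS_NAMES[cls]
)
N_FEATURES = len(CANONICAL_ORDER)
assert N_FEATURES == 93


@dataclass
class ExtractorConfig:
    """Knobs of the feature extractor (discretization range and matrix options)."""

    lo_gy: float = 0.0
    hi_gy: float = 70.0
    n_levels: int = 70
    gldm_alpha: int = 0


@dataclass
class FeatureVector:
    """93 named feature values for one (dose, ROI) pair, in canonical order."""

    values: np.ndarray  # (93,)
    valid: np.ndarray  # (93,) bool

    def __getitem__(self, key: tuple[str, str]) -> float:
        return float(self.values[CANONICAL_ORDER.index(key)])

    def is_valid(self, key: tuple[str, str]) -> bool:
        return bool(self.valid[CANONICAL_ORDER.index(key)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_class": [c for c, _ in CANONICAL_ORDER],
            "feature_name": [n for _, n in CANONICAL_ORDER],
            "value": self.values,
            "valid": self.valid,
        })

    def __len__(self) -> int:
        return N_FEATURES


def _plog2p(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------- first order

def _firstorder(dose: np.ndarray, droi: DiscretizedRoi, voxel_volume: float) -> dict:
    x = dose
    n = x.size
    mean = x.mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = x.var()  # population
    hist = np.bincount(droi.in_mask_levels - 1, minlength=droi.n_levels)
    p = hist / n
    energy = float(np.sum(x * x))
    robust = x[(x >= p10) & (x <= p90)]
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": _plog2p(p),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x * x))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p * p)),
    }


# ----------------------------------------------------------------------- GLCM

def _glcm_one(counts: np.ndarray, ng_present: int) -> dict:
    # Crop to gray levels with any co-occurrence mass: every feature below is
    # invariant to empty rows/columns because actual level values are kept.
    row_mass = counts.sum(axis=1)
    present_rows = np.flatnonzero(row_mass > 0)
    iv = (present_rows + 1).astype(np.float64)
    counts = counts[np.ix_(present_rows, present_rows)]
    total = counts.sum()
    p = counts / total
    px = p.sum(axis=1)
    mu = float(np.sum(iv * px))
    sigma2 = float(np.sum((iv - mu) ** 2 * px))
    ii, jj = np.meshgrid(iv, iv, indexing="ij")

    # diagonal (difference) and cross-diagonal (sum) probabilities
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()
    sum_idx = (ii + jj).astype(np.int64).ravel()
    max_level = int(iv[-1])
    kd = np.arange(0, max_level, dtype=np.float64)
    pxmy = np.bincount(diff_idx, weights=p.ravel(), minlength=max_level)[:max_level]
    ks = np.arange(0, 2 * max_level + 1, dtype=np.float64)
    pxpy = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * max_level + 1)

    autocorr = float(np.sum(ii * jj * p))
    clus = ii + jj - 2 * mu
    da = float(np.sum(kd * pxmy))
    joint_entropy = _plog2p(p.ravel())

    hx = _plog2p(px)
    nz = p > 0
    pxpy_outer = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.sum(p[nz] * np.log2(pxpy_outer[nz])))
    hxy2 = _plog2p(pxpy_outer.ravel())
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0  # HX == HY (symmetric)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if sigma2 > 1e-14:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0

    # Maximal correlation coefficient: second-largest eigenvalue of Q.
    present = px > 0
    if present.sum() > 1:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
        q = (ps / pxs[:, None]) @ (ps / pxs[:, None])
        eig = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    inv_var_mask = kd >= 1
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float(np.sum(clus**4 * p)),
        "ClusterShade": float(np.sum(clus**3 * p)),
        "ClusterTendency": float(np.sum(clus**2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": _plog2p(pxmy),
        "DifferenceVariance": float(np.sum((kd - da) ** 2 * pxmy)),
        "JointEnergy": float(np.sum(p * p)),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(pxmy / (1.0 + kd**2))),
        "Idmn": float(np.sum(pxmy / (1.0 + (kd / ng_present) ** 2))),
        "Id": float(np.sum(pxmy / (1.0 + kd))),
        "Idn": float(np.sum(pxmy / (1.0 + kd / ng_present))),
        "InverseVariance": float(np.sum(pxmy[inv_var_mask] / kd[inv_var_mask] ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ks * pxpy)),
        "SumEntropy": _plog2p(pxpy),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


# ----------------------------------------------------- run/zone/dependence

def _rzd_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict:
    """Shared Σ P(i,j)·w(i,j) machinery for GLRLM ('Run'), GLSZM ('Zone',
    'Area') and GLDM ('Dependence') matrices: i = gray level, j = run length /
    zone size / dependence."""
    ns = mat.sum()
    iv = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    jv = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ri = mat.sum(axis=1)  # per gray level
    rj = mat.sum(axis=0)  # per size
    p = mat / ns
    pi = ri / ns
    pj = rj / ns
    mu_i = float(np.sum(iv * pi))
    mu_j = float(np.sum(jv * pj))

    small = float(np.sum(rj / jv**2) / ns)
    large = float(np.sum(rj * jv**2) / ns)
    low = float(np.sum(ri / iv**2) / ns)
    high = float(np.sum(ri * iv**2) / ns)
    sl = float(np.sum(mat / np.outer(iv**2, jv**2)) / ns)
    sh = float(np.sum(mat * np.outer(iv**2, 1.0 / jv**2)) / ns)
    ll = float(np.sum(mat * np.outer(1.0 / iv**2, jv**2)) / ns)
    lh = float(np.sum(mat * np.outer(iv**2, jv**2)) / ns)
    gln = float(np.sum(ri**2) / ns)
    glnn = float(np.sum(ri**2) / ns**2)
    sn = float(np.sum(rj**2) / ns)
    snn = float(np.sum(rj**2) / ns**2)
    glv = float(np.sum((iv - mu_i) ** 2 * pi))
    sv = float(np.sum((jv - mu_j) ** 2 * pj))
    entropy = _plog2p(p.ravel())

    if kind == "glrlm":
        return {
            "ShortRunEmphasis": small, "LongRunEmphasis": large,
            "LowGrayLevelRunEmphasis": low, "HighGrayLevelRunEmphasis": high,
            "ShortRunLowGrayLevelEmphasis": sl, "ShortRunHighGrayLevelEmphasis": sh,
            "LongRunLowGrayLevelEmphasis": ll, "LongRunHighGrayLevelEmphasis": lh,
            "GrayLevelNonUniformity": gln, "GrayLevelNonUniformityNormalized": glnn,
            "RunLengthNonUniformity": sn, "RunLengthNonUniformityNormalized": snn,
            "RunPercentage": float(ns / n_voxels), "GrayLevelVariance": glv,
            "RunVariance": sv, "RunEntropy": entropy,
        }
    if kind == "glszm":
        return {
            "SmallAreaEmphasis": small, "LargeAreaEmphasis": large,
            "LowGrayLevelZoneEmphasis": low, "HighGrayLevelZoneEmphasis": high,
            "SmallAreaLowGrayLevelEmphasis": sl, "SmallAreaHighGrayLevelEmphasis": sh,
            "LargeAreaLowGrayLevelEmphasis": ll, "LargeAreaHighGrayLevelEmphasis": lh,
            "GrayLevelNonUniformity": gln, "GrayLevelNonUniformityNormalized": glnn,
            "SizeZoneNonUniformity": sn, "SizeZoneNonUniformityNormalized": snn,
            "ZonePercentage": float(ns / n_voxels), "GrayLevelVariance": glv,
            "ZoneVariance": sv, "ZoneEntropy": entropy,
        }
    # gldm: 14 features, no normalized gray-level non-uniformity, no percentage
    return {
        "SmallDependenceEmphasis": small, "LargeDependenceEmphasis": large,
        "LowGrayLevelEmphasis": low, "HighGrayLevelEmphasis": high,
        "SmallDependenceLowGrayLevelEmphasis": sl,
        "SmallDependenceHighGrayLevelEmphasis": sh,
        "LargeDependenceLowGrayLevelEmphasis": ll,
        "LargeDependenceHighGrayLevelEmphasis": lh,
        "GrayLevelNonUniformity": gln,
        "DependenceNonUniformity": sn, "DependenceNonUniformityNormalized": snn,
        "GrayLevelVariance": glv, "DependenceVariance": sv,
        "DependenceEntropy": entropy,
    }


# ---------------------------------------------------------------------- NGTDM

def _ngtdm_features(s: np.ndarray, n: np.ndarray, ng_present_unused: int) -> dict:
    nvp = n.sum()
    p = n / nvp
    present = p > 0
    iv = np.arange(1, s.size + 1, dtype=np.float64)
    ip = iv[present]
    pp = p[present]
    sp = s[present]
    ngp = int(present.sum())

    coarse_denom = float(np.sum(pp * sp))
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = (
            float(np.sum(pp[:, None] * pp[None, :] * di**2)) / (ngp * (ngp - 1))
        ) * (float(s.sum()) / nvp)
        busy_denom = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0
        pair_num = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        pair_den = pp[:, None] + pp[None, :]
        complexity = float(np.sum(np.abs(di) * pair_num / pair_den)) / nvp
        s_sum = float(s.sum())
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
        "Complexity": complexity, "Strength": strength,
    }


# ------------------------------------------------------------------ extractor

def extract_features(
    grid: DoseGrid,
    mask: RoiMask,
    config: ExtractorConfig | None = None,
) -> FeatureVector:
    """Compute the canonical 93-feature vector for one (dose, ROI) pair."""
    cfg = config if config is not None else ExtractorConfig()
    droi = discretize(grid, mask, cfg.lo_gy, cfg.hi_gy, cfg.n_levels)
    mats = build_texture_matrices(droi, alpha=cfg.gldm_alpha)
    dose_in = grid.values[mask.values]
    ng_present = int(np.unique(droi.in_mask_levels).size)

    out: dict[tuple[str, str], float] = {}
    valid: dict[tuple[str, str], bool] = {}

    fo = _firstorder(dose_in, droi, grid.voxel_volume)
    for k, v in fo.items():
        out[("firstorder", k)] = v
        valid[("firstorder", k)] = True

    # GLCM / GLRLM: per-direction features averaged over directions that have
    # at least one pair/run; a ROI with no neighboring pairs in any direction
    # (single voxel) leaves the class flagged invalid.
    glcm_dirs = [d for d in range(13) if mats.glcm[d].sum() > 0]
    if glcm_dirs:
        per_dir = [_glcm_one(mats.glcm[d], ng_present) for d in glcm_dirs]
        for name in GLCM_NAMES:
            out[("glcm", name)] = float(np.mean([f[name] for f in per_dir]))
            valid[("glcm", name)] = True
    else:
        for name in GLCM_NAMES:
            out[("glcm", name)] = np.nan
            valid[("glcm", name)] = False

    glrlm_dirs = [d for d in range(13) if mats.glrlm[d].sum() > 0]
    if glrlm_dirs:
        per_dir = [
            _rzd_features(mats.glrlm[d], mats.n_voxels, "glrlm") for d in glrlm_dirs
        ]
        for name in GLRLM_NAMES:
            out[("glrlm", name)] = float(np.mean([f[name] for f in per_dir]))
            valid[("glrlm", name)] = True
    else:
        for name in GLRLM_NAMES:
            out[("glrlm", name)] = np.nan
            valid[("glrlm", name)] = False

    for name, v in _rzd_features(mats.glszm, mats.n_voxels, "glszm").items():
        out[("glszm", name)] = v
        valid[("glszm", name)] = True

    if mats.ngtdm_n.sum() > 0:
        for name, v in _ngtdm_features(mats.ngtdm_s, mats.ngtdm_n, ng_present).items():
            out[("ngtdm", name)] = v
            valid[("ngtdm", name)] = True
    else:
        for name in NGTDM_NAMES:
            out[("ngtdm", name)] = np.nan
            valid[("ngtdm", name)] = False

    for name, v in _rzd_features(mats.gldm, mats.n_voxels, "gldm").items():
        out[("gldm", name)] = v
        valid[("gldm", name)] = True

    values = np.array([out[key] for key in CANONICAL_ORDER])
    flags = np.array([valid[key] for key in CANONICAL_ORDER])
    return FeatureVector(values=values, valid=flags)
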