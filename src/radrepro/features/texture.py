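"""Texture features from the five gray-level matrices.

GLCM and GLRLM features are computed per direction (13 unique 3D directions)
and averaged with equal weight over the directions that contain at least one
pair/run; GLSZM, GLDM and NGTDM are single-matrix classes. Quantities whose
denominator degenerates (single gray level, single voxel, empty matrix)
return 0 by convention, with a warning, so downstream tables never carry
NaN.
"""

from __future__ import annotations

import warnings

import numpy as np

from .discretize import DiscretizedRoi
from .matrices import gldm_matrix, glcm_stack, glrlm_stack, glszm_matrix, ngtdm_table

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)

GLCM_NAMES: tuple[str, ...] = (
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


def _warn_degenerate(cls: str) -> None:
    warnings.warn(
        f"{cls}: degenerate ROI (no valid neighbour pairs); features reported as 0",
        stacklevel=3,
    )


def _glcm_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(ii * p))
    uy = float(np.sum(jj * p))
    sx = np.sqrt(np.sum(((i - ux) ** 2) * px))
    sy = np.sqrt(np.sum(((i - uy) ** 2) * py))

    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| = 0..ng-1
    pxy_diff = np.zeros(ng)
    np.add.at(pxy_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    pxy_sum = np.zeros(2 * ng - 1)
    np.add.at(pxy_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    hxy = float(-np.sum(p * np.log2(p + _EPS)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))

    da = float(np.sum(k_diff * pxy_diff))
    corr_num = float(np.sum(ii * jj * p)) - ux * uy

    # MCC: sqrt of the second-largest eigenvalue of Q
    if ng > 1 and np.all(px > 0):
        q = (p / px[:, None]) @ (p / py[None, :]).T
        ev = np.sort(np.linalg.eigvals(q).real)[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0)))
    elif ng > 1:
        nz = px > 0
        if nz.sum() > 1:
            psub = p[np.ix_(nz, nz)]
            q = (psub / px[nz][:, None]) @ (psub / py[nz][None, :]).T
            ev = np.sort(np.linalg.eigvals(q).real)[::-1]
            mcc = float(np.sqrt(max(ev[1], 0.0)))
        else:
            mcc = 0.0
    else:
        mcc = 0.0

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    inv_var = float(np.sum(pxy_diff[1:] / (k_diff[1:] ** 2))) if ng > 1 else 0.0

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum(((ii + jj - ux - uy) ** 4) * p)),
        "ClusterShade": float(np.sum(((ii + jj - ux - uy) ** 3) * p)),
        "ClusterTendency": float(np.sum(((ii + jj - ux - uy) ** 2) * p)),
        "Contrast": float(np.sum(((ii - jj) ** 2) * p)),
        "Correlation": corr_num / (sx * sy) if sx * sy > 0 else 0.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(pxy_diff * np.log2(pxy_diff + _EPS))),
        "DifferenceVariance": float(np.sum(((k_diff - da) ** 2) * pxy_diff)),
        "Id": float(np.sum(pxy_diff / (1.0 + k_diff))),
        "Idm": float(np.sum(pxy_diff / (1.0 + k_diff**2))),
        "Idmn": float(np.sum(pxy_diff / (1.0 + (k_diff**2) / ng**2))),
        "Idn": float(np.sum(pxy_diff / (1.0 + k_diff / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p * p)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * pxy_sum)),
        "SumEntropy": float(-np.sum(pxy_sum * np.log2(pxy_sum + _EPS))),
        "SumSquares": float(np.sum(((ii - ux) ** 2) * p)),
    }


def glcm_features(disc: DiscretizedRoi) -> dict[str, float]:
    """24 co-occurrence features, averaged over valid directions."""
    stack = glcm_stack(disc.levels, disc.n_levels)
    per_dir = []
    for mat in stack:
        tot = mat.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_single(mat / tot, disc.n_levels))
    if not per_dir:
        _warn_degenerate("GLCM")
        return {name: 0.0 for name in GLCM_NAMES}
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


GLRLM_NAMES: tuple[str, ...] = (
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


def _weighted_matrix_features(
    mat: np.ndarray,
    n_voxels: int,
    names: dict[str, str],
) -> dict[str, float]:
    """Shared formula family of GLRLM/GLSZM/GLDM.

    ``mat[i - 1, j - 1]`` holds counts for gray level ``i`` and size/length/
    dependence ``j``; ``names`` maps the generic keys to the class-specific
    feature names (absent keys are skipped).
    """
    ns = mat.sum()
    ng, nj = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nj + 1, dtype=np.float64)[None, :]
    p = mat / ns
    gl_marg = mat.sum(axis=1)
    sz_marg = mat.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    pz = p[p > 0]
    generic = {
        "small": float(np.sum(mat / j**2) / ns),
        "large": float(np.sum(mat * j**2) / ns),
        "gln": float(np.sum(gl_marg**2) / ns),
        "glnn": float(np.sum(gl_marg**2) / ns**2),
        "szn": float(np.sum(sz_marg**2) / ns),
        "sznn": float(np.sum(sz_marg**2) / ns**2),
        "pct": float(ns / n_voxels),
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "szv": float(np.sum(p * (j - mu_j) ** 2)),
        "ent": float(-np.sum(pz * np.log2(pz + _EPS))),
        "lgl": float(np.sum(mat / i**2) / ns),
        "hgl": float(np.sum(mat * i**2) / ns),
        "sl": float(np.sum(mat / (i**2 * j**2)) / ns),
        "sh": float(np.sum(mat * i**2 / j**2) / ns),
        "ll": float(np.sum(mat * j**2 / i**2) / ns),
        "lh": float(np.sum(mat * i**2 * j**2) / ns),
    }
    return {out_name: generic[key] for key, out_name in names.items()}


_GLRLM_MAP = {
    "small": "ShortRunEmphasis",
    "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "RunLengthNonUniformity",
    "sznn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage",
    "glv": "GrayLevelVariance",
    "szv": "RunVariance",
    "ent": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "sl": "ShortRunLowGrayLevelEmphasis",
    "sh": "ShortRunHighGrayLevelEmphasis",
    "ll": "LongRunLowGrayLevelEmphasis",
    "lh": "LongRunHighGrayLevelEmphasis",
}


def glrlm_features(disc: DiscretizedRoi) -> dict[str, float]:
    """16 run-length features, averaged over valid directions."""
    stack = glrlm_stack(disc.levels, disc.n_levels)
    n_vox = disc.n_voxels
    per_dir = [
        _weighted_matrix_features(mat, n_vox, _GLRLM_MAP) for mat in stack if mat.sum() > 0
    ]
    if not per_dir:
        _warn_degenerate("GLRLM")
        return {name: 0.0 for name in GLRLM_NAMES}
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}


GLSZM_NAMES: tuple[str, ...] = (
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

_GLSZM_MAP = {
    "small": "SmallAreaEmphasis",
    "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "SizeZoneNonUniformity",
    "sznn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "szv": "ZoneVariance",
    "ent": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "sl": "SmallAreaLowGrayLevelEmphasis",
    "sh": "SmallAreaHighGrayLevelEmphasis",
    "ll": "LargeAreaLowGrayLevelEmphasis",
    "lh": "LargeAreaHighGrayLevelEmphasis",
}


def glszm_features(disc: DiscretizedRoi) -> dict[str, float]:
    """16 size-zone features (26-connected zones, single matrix)."""
    mat = glszm_matrix(disc.levels, disc.n_levels)
    if mat.sum() == 0:
        _warn_degenerate("GLSZM")
        return {name: 0.0 for name in GLSZM_NAMES}
    return _weighted_matrix_features(mat, disc.n_voxels, _GLSZM_MAP)


GLDM_NAMES: tuple[str, ...] = (
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

_GLDM_MAP = {
    "small": "SmallDependenceEmphasis",
    "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "szn": "DependenceNonUniformity",
    "sznn": "DependenceNonUniformityNormalized",
    "glv": "GrayLevelVariance",
    "szv": "DependenceVariance",
    "ent": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis",
    "sl": "SmallDependenceLowGrayLevelEmphasis",
    "sh": "SmallDependenceHighGrayLevelEmphasis",
    "ll": "LargeDependenceLowGrayLevelEmphasis",
    "lh": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(disc: DiscretizedRoi, alpha: int = 0) -> dict[str, float]:
    """14 dependence features (26-neighbourhood, threshold ``alpha``)."""
    mat = gldm_matrix(disc.levels, disc.n_levels, alpha=alpha)
    if mat.sum() == 0:
        _warn_degenerate("GLDM")
        return {name: 0.0 for name in GLDM_NAMES}
    return _weighted_matrix_features(mat, disc.n_voxels, _GLDM_MAP)


NGTDM_NAMES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

#: Reported coarseness when every neighbourhood difference is 0.
COARSENESS_CAP = 1e6


def ngtdm_features(disc: DiscretizedRoi) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features."""
    table = ngtdm_table(disc.levels, disc.n_levels)
    n_vox = disc.n_voxels
    if n_vox == 0 or table[:, 0].sum() == 0:
        _warn_degenerate("NGTDM")
        return {name: 0.0 for name in NGTDM_NAMES}
    nz = table[:, 0] > 0
    i = np.arange(1, disc.n_levels + 1, dtype=np.float64)[nz]
    p = table[nz, 1]
    s = table[nz, 2]
    ngp = int(nz.sum())

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        dif2 = (i[:, None] - i[None, :]) ** 2
        pij = p[:, None] * p[None, :]
        contrast = float(np.sum(pij * dif2) / (ngp * (ngp - 1)) * (s.sum() / n_vox))
        busy_den = float(np.sum(np.abs((i * p)[:, None] - (i * p)[None, :])))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(i[:, None] - i[None, :])
        pis = p * s
        complexity = float(
            np.sum(absdif * (pis[:, None] + pis[None, :]) / (p[:, None] + p[None, :])) / n_vox
        )
        s_sum = float(s.sum())
        strength = (
            float(np.sum((p[:, None] + p[None, :]) * dif2)) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
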