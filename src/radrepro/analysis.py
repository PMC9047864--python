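"""Tumor-vs-peritumor comparison of robust features and PCA reduction.

Group comparison routes through Shapiro–Wilk normality (alpha = 0.05 per
group): one-way ANOVA when both groups look normal, Kruskal–Wallis
otherwise, significance at p < 0.05. PCA is performed on the z-scored
(correlation-matrix) feature matrix; ``n90`` is the smallest number of
leading components whose cumulative explained-variance proportion reaches
90%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "GroupComparisonResult",
    "PcaResult",
    "compare_tissues",
    "pca_reduce",
    "n_components_for",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one tumor-vs-peritumor feature comparison."""

    feature: str
    test: str  # "anova" | "kruskal" | "degenerate"
    statistic: float
    p_value: float
    significant: bool
    mean_tumor: float
    mean_peritumor: float


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= ALPHA


def compare_tissues(
    tumor, peritumor, feature: str = "", alpha: float = ALPHA
) -> GroupComparisonResult:
    """Compare one feature between tumor and peritumoral samples.

    Uses one-way ANOVA when both groups pass Shapiro–Wilk normality at the
    5% level, Kruskal–Wallis otherwise. Two identical constant groups are
    reported as degenerate with p = 1.
    """
    a = np.asarray(tumor, dtype=np.float64)
    b = np.asarray(peritumor, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_tissues requires >= 3 observations per group")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparisonResult(
            feature, "degenerate", 0.0, 1.0, False, float(a.mean()), float(b.mean())
        )
    if _is_normal(a) and _is_normal(b):
        test = "anova"
        stat, p = sps.f_oneway(a, b)
    else:
        test = "kruskal"
        stat, p = sps.kruskal(a, b)
    p = float(p)
    return GroupComparisonResult(
        feature=feature,
        test=test,
        statistic=float(stat),
        p_value=p,
        significant=p < alpha,
        mean_tumor=float(a.mean()),
        mean_peritumor=float(b.mean()),
    )


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA of a subjects x features matrix."""

    eigenvalues: np.ndarray  # descending
    proportions: np.ndarray  # explained-variance fractions, sum to 1
    cumulative: np.ndarray
    scores: np.ndarray  # subjects x components
    feature_names: tuple[str, ...]
    n90: int

    def summary(self) -> str:
        lines = ["component  eigenvalue  proportion  cumulative"]
        for i, (ev, pr, cu) in enumerate(
            zip(self.eigenvalues, self.proportions, self.cumulative), start=1
        ):
            lines.append(f"PC{i:<8d} {ev:10.4f}  {100 * pr:9.2f}%  {100 * cu:9.2f}%")
        lines.append(f"components for >= 90% variance: {self.n90}")
        return "\n".join(lines)


def pca_reduce(features, feature_names=None, fraction: float = 0.90) -> PcaResult:
    """PCA of a subjects x features matrix after column z-scoring.

    Zero-variance columns are dropped with a warning before z-scoring.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("pca_reduce requires a 2D matrix with >= 2 subjects, >= 1 feature")
    names = (
        tuple(feature_names)
        if feature_names is not None
        else tuple(f"f{j}" for j in range(x.shape[1]))
    )
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance feature(s) before PCA: {dropped}", stacklevel=2)
        x = x[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)
    if x.shape[1] == 0:
        raise ValueError("all features have zero variance; PCA undefined")
    z = (x - x.mean(axis=0)) / x.std(axis=0)

    model = PCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(z)
    eig = model.explained_variance_
    prop = model.explained_variance_ratio_
    cum = np.cumsum(prop)
    return PcaResult(
        eigenvalues=eig,
        proportions=prop,
        cumulative=cum,
        scores=scores,
        feature_names=names,
        n90=_n_for(cum, fraction),
    )


def _n_for(cumulative: np.ndarray, fraction: float) -> int:
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    hit = np.nonzero(cumulative >= fraction - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else len(cumulative)


def n_components_for(pca: PcaResult, fraction: float = 0.90) -> int:
    """Smallest number of leading components reaching ``fraction`` of variance."""
    return _n_for(pca.cumulative, fraction)
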