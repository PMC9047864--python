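"""First-order intensity statistics (18 features).

Computed from the raw ROI intensities; the two histogram features (entropy,
uniformity) use the fixed-bin-width discretized levels. Moments are
population moments (no small-sample bias correction), matching the radiomics
reference definitions the study relies on.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

_EPS = np.spacing(1.0)


def first_order_features(disc: DiscretizedRoi) -> dict[str, float]:
    """The 18 first-order features of an ROI.

    Skewness and kurtosis of a constant ROI are reported as 0 by convention
    (the central second moment vanishes).
    """
    x = disc.intensities
    n = x.size
    if n == 0:
        raise ValueError("first-order features require a non-empty ROI")
    vox = float(np.prod(disc.spacing))

    p = disc.level_histogram().astype(np.float64)
    p = p[p > 0] / n

    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    p10, p25, p75, p90 = (float(v) for v in np.percentile(x, (10, 25, 75, 90)))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    energy = float(np.sum(x * x))
    out = {
        "Energy": energy,
        "TotalEnergy": vox * energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float(np.sum(p * p)),
    }
    return out
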