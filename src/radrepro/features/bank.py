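"""Assembly of the full 107-feature radiomic vector.

Feature names follow the ``class_FeatureName`` convention in a fixed,
documented order: 18 first-order, 14 shape, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM and 5 NGTDM features. Definitions follow the open radiomics
reference feature set (original image only, no filtered-image features, no
resampling), with fixed-bin-width discretization shared by all texture
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import ImageVolume, RoiMask, validate_alignment
from .discretize import DiscretizedRoi, discretize_fixed_bin_width
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["FEATURE_CLASSES", "ALL_FEATURE_NAMES", "FeatureVector", "extract_all"]

FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items() for name in names
)

assert len(ALL_FEATURE_NAMES) == 107


@dataclass(frozen=True)
class FeatureVector:
    """Ordered map of the 107 named feature values."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values) != ALL_FEATURE_NAMES:
            missing = set(ALL_FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(ALL_FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry exactly the 107 canonical names in order; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def by_class(self, cls: str) -> dict[str, float]:
        prefix = cls + "_"
        return {k: v for k, v in self.values.items() if k.startswith(prefix)}

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in ALL_FEATURE_NAMES])


def extract_all(
    image: ImageVolume,
    mask: RoiMask,
    bin_width: float = 25.0,
    gldm_alpha: int = 0,
    disc: DiscretizedRoi | None = None,
) -> FeatureVector:
    """Extract the full 107-feature vector from an aligned image/mask pair.

    Parameters
    ----------
    image, mask
        Aligned volume and non-empty binary ROI.
    bin_width
        Fixed bin width of the gray-level discretization (default 25).
    gldm_alpha
        Dependence threshold of the GLDM (default 0: equal levels only).
    disc
        Pre-computed discretization, to avoid repeating it when several
        feature classes are requested separately.
    """
    report = validate_alignment(image, mask)
    if not report.aligned:
        raise ValueError("image/mask misaligned: " + "; ".join(report.mismatches))
    if mask.is_empty():
        raise ValueError("cannot extract features from an empty mask")
    if disc is None:
        disc = discretize_fixed_bin_width(image, mask, bin_width)

    stages = {
        "firstorder": lambda: first_order_features(disc),
        "shape": lambda: shape_features(mask),
        "glcm": lambda: glcm_features(disc),
        "glrlm": lambda: glrlm_features(disc),
        "glszm": lambda: glszm_features(disc),
        "gldm": lambda: gldm_features(disc, alpha=gldm_alpha),
        "ngtdm": lambda: ngtdm_features(disc),
    }
    values: dict[str, float] = {}
    for cls, run in stages.items():
        try:
            result = run()
        except Exception as exc:  # re-raise with the feature-class context
            raise RuntimeError(f"feature class '{cls}' failed: {exc}") from exc
        for name in FEATURE_CLASSES[cls]:
            values[f"{cls}_{name}"] = float(result[name])
    return FeatureVector(values)
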