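"""Fixed-bin-width gray-level discretization of an ROI.

Intensities are mapped to integer gray levels with a constant bin width
(default 25 HU-like units), anchored at the ROI minimum::

    level(x) = floor(x / w) - floor(min_ROI / w) + 1

so the lowest occupied bin is level 1 and levels are comparable across ROIs
up to a shift by whole bins. This "absolute" discretization is the standard
fixed-bin-width rule of the radiomics reference implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import ImageVolume, RoiMask

__all__ = ["DiscretizedRoi", "discretize_fixed_bin_width"]


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer gray levels of an ROI, cropped to the mask bounding box.

    Attributes
    ----------
    levels
        3D int array over the mask bounding box; values 1..n_levels inside
        the ROI, 0 outside.
    n_levels
        Highest occupied level (N_g).
    bin_width
        Intensity width of one gray level.
    intensities
        1D array of the raw ROI intensities (same voxel order as
        ``levels[levels > 0]``).
    spacing
        Voxel spacing in mm, carried through for texture features that need
        physical geometry.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    intensities: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))

    @property
    def roi_levels(self) -> np.ndarray:
        """1D array of levels of foreground voxels only."""
        return self.levels[self.levels > 0]

    def level_histogram(self) -> np.ndarray:
        """Counts per level 1..n_levels (length ``n_levels``)."""
        return np.bincount(self.roi_levels, minlength=self.n_levels + 1)[1:]


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)


def discretize_fixed_bin_width(
    image: ImageVolume, mask: RoiMask, bin_width: float = 25.0
) -> DiscretizedRoi:
    """Discretize the intensities of ``image`` under ``mask``.

    Raises
    ------
    ValueError
        If the mask is empty or the bin width is not positive.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    fg = mask.array.astype(bool)
    if not fg.any():
        raise ValueError("cannot discretize an empty ROI mask")
    bb = _bounding_box(fg)
    img = image.array[bb]
    sub = fg[bb]
    vals = img[sub]
    # floor-anchored binning: identical up to a whole-bin intensity shift
    lo = np.floor(vals.min() / bin_width)
    lev = (np.floor(img / bin_width) - lo + 1).astype(np.int64)
    levels = np.where(sub, lev, 0)
    return DiscretizedRoi(
        levels=levels,
        n_levels=int(levels.max()),
        bin_width=float(bin_width),
        intensities=np.asarray(vals, dtype=np.float64),
        spacing=mask.spacing,
    )
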