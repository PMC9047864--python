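"""Image/mask containers and peritumoral-ring construction on anisotropic grids.

All geometry is expressed in physical millimetres: a voxel with index
``(i, j, k)`` sits at ``origin + index * spacing``.  Distances between masks
are spacing-weighted Euclidean distances between voxel centres, which is what
"a ring of radius r mm" means on a grid with anisotropic spacing such as the
0.97 x 0.97 x 3.0 mm CT grids this package emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "RoiMask",
    "peritumoral_ring",
    "mask_volume_mm3",
    "validate_alignment",
    "dice",
]

#: Spacing/origin agreement tolerance for alignment checks, in mm.
GEOMETRY_TOL_MM = 1e-4


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar voxel grid with physical spacing.

    Parameters
    ----------
    array
        3D float array of voxel intensities (HU-like units).
    spacing
        Physical size of one voxel along each axis, mm. Strictly positive.
    origin
        Physical position of voxel (0, 0, 0), mm.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("image array must be a non-empty 3D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "array", arr.astype(np.float64, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiMask:
    """A binary voxel mask aligned to an :class:`ImageVolume` grid."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("mask array must be a non-empty 3D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            bad = [v for v in uniq if v not in (0, 1)]
            raise ValueError(f"mask must be binary; found value(s) {bad}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "array", arr.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    def is_empty(self) -> bool:
        return self.n_voxels == 0


def mask_volume_mm3(mask: RoiMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Physical volume of a mask: foreground voxel count x voxel volume (mm^3)."""
    sp = mask.spacing if spacing is None else spacing
    return float(int(np.asarray(mask.array).sum()) * np.prod(sp))


def peritumoral_ring(
    gtv: RoiMask,
    spacing: tuple[float, float, float] | None = None,
    radius_mm: float = 5.0,
    clip_mask: RoiMask | None = None,
) -> RoiMask:
    """Build the 0-to-``radius_mm`` mm shell of tissue surrounding a GTV.

    A voxel belongs to the ring iff its spacing-weighted Euclidean distance to
    the nearest GTV voxel centre is > 0 and <= ``radius_mm``. The ring is by
    construction disjoint from the GTV and clipped at the grid boundary.

    Parameters
    ----------
    gtv
        Non-empty gross-tumour-volume mask.
    spacing
        Override spacing (mm). Defaults to the mask's own spacing.
    radius_mm
        Outer radius of the shell in mm (default 5, the peritumoral margin).
    clip_mask
        Optional body/organ mask to intersect the ring with; the study this
        package emulates does not state such clipping, so the default is none.
    """
    if gtv.is_empty():
        raise ValueError("cannot build a peritumoral ring around an empty GTV mask")
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be > 0, got {radius_mm}")
    sp = gtv.spacing if spacing is None else tuple(float(s) for s in spacing)

    fg = gtv.array.astype(bool)
    # EDT of the background gives, for every voxel, the mm distance to the GTV.
    dist = ndimage.distance_transform_edt(~fg, sampling=sp)
    ring = (dist > 0) & (dist <= radius_mm)
    if clip_mask is not None:
        ring &= clip_mask.array.astype(bool)
    if not ring.any():
        warnings.warn(
            f"peritumoral ring of radius {radius_mm} mm is empty at spacing {sp}; "
            "the radius is below the coarsest voxel step",
            stacklevel=2,
        )
    return RoiMask(ring.astype(np.uint8), sp, gtv.origin)


@dataclass
class AlignmentReport:
    """Mismatches between an image grid and a mask grid; empty means aligned."""

    mismatches: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy iff aligned
        return not self.mismatches

    @property
    def aligned(self) -> bool:
        return not self.mismatches


_AXES = ("axis 0", "axis 1", "axis 2")


def validate_alignment(image: ImageVolume, mask: RoiMask) -> AlignmentReport:
    """Check that a mask lives on its image's grid (shape, spacing, origin)."""
    report = AlignmentReport()
    for ax in range(3):
        if image.shape[ax] != mask.shape[ax]:
            report.mismatches.append(
                f"shape mismatch on {_AXES[ax]}: image {image.shape[ax]} vs mask {mask.shape[ax]}"
            )
        if abs(image.spacing[ax] - mask.spacing[ax]) > GEOMETRY_TOL_MM:
            report.mismatches.append(
                f"spacing mismatch on {_AXES[ax]}: image {image.spacing[ax]} vs "
                f"mask {mask.spacing[ax]} (tol {GEOMETRY_TOL_MM} mm)"
            )
        if abs(image.origin[ax] - mask.origin[ax]) > GEOMETRY_TOL_MM:
            report.mismatches.append(
                f"origin mismatch on {_AXES[ax]}: image {image.origin[ax]} vs "
                f"mask {mask.origin[ax]} (tol {GEOMETRY_TOL_MM} mm)"
            )
    return report


def dice(a: RoiMask | np.ndarray, b: RoiMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) between two binary masks."""
    aa = (a.array if isinstance(a, RoiMask) else np.asarray(a)).astype(bool)
    bb = (b.array if isinstance(b, RoiMask) else np.asarray(b)).astype(bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(aa, bb).sum() / denom)
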