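"""3D shape features (14) of a binary mask on an anisotropic grid.

Surface quantities come from a triangulated isosurface of the mask (marching
cubes at level 0.5 on the zero-padded mask, in physical mm); axis lengths
come from the principal components of the foreground voxel-centre
coordinates. Maximum 2D diameters are in-plane diameters: the largest
pairwise voxel-centre distance within any single plane perpendicular to the
excluded axis (axis 2 is the slice axis under the default 0.97x0.97x3.0 mm
spacing).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..geometry import RoiMask

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES: tuple[str, ...] = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated isosurface of the mask in physical mm.

    The surface is the zero level of the lightly smoothed, spacing-aware
    signed distance of the mask: marching cubes on the raw binary mask
    produces staircase facets that overestimate surface area by ~9% even
    for large spheres, while the smoothed signed distance restores
    sub-voxel surface placement. The 0.5-voxel kernel is small enough that
    one-voxel-thin structures keep a valid surface; should smoothing ever
    remove the zero crossing, the binary surface is used as a fallback.
    """
    from scipy import ndimage

    fg = np.pad(mask.astype(bool), 2)
    sdf = ndimage.distance_transform_edt(~fg, sampling=spacing) - ndimage.distance_transform_edt(
        fg, sampling=spacing
    )
    smooth = ndimage.gaussian_filter(sdf, sigma=0.5)
    if (smooth < 0).any():
        verts, faces, _, _ = measure.marching_cubes(-smooth, level=0.0, spacing=spacing)
    else:
        verts, faces, _, _ = measure.marching_cubes(
            np.pad(mask.astype(np.float64), 2), level=0.5, spacing=spacing
        )
    offs = 2 * np.asarray(spacing, dtype=np.float64)
    return verts - offs, faces  # undo the 2-voxel pad shift


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _surface_area(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def shape_features(mask: RoiMask, spacing=None) -> dict[str, float]:
    """The 14 reference 3D shape features of a mask, in mm-based units.

    Single-voxel (or otherwise degenerate) masks yield 0 for PCA-based axis
    lengths, with a warning.
    """
    sp = mask.spacing if spacing is None else tuple(float(s) for s in spacing)
    fg = mask.array.astype(bool)
    if not fg.any():
        raise ValueError("shape features require a non-empty mask")
    # crop to the bounding box so results do not depend on where the ROI
    # sits inside the grid
    bb = tuple(slice(int(a.min()), int(a.max()) + 1) for a in np.nonzero(fg))
    fg = fg[bb]

    verts, faces = _mesh(fg, sp)
    mesh_v = _mesh_volume(verts, faces)
    area = _surface_area(verts, faces)
    voxel_v = float(fg.sum() * np.prod(sp))

    # in-plane diameters from physical boundary voxel centres, grouped by the
    # excluded axis so each diameter lives in one plane
    bnd = _boundary_voxels(fg)
    phys = bnd * np.asarray(sp)
    d3 = _max_pairwise(verts)
    diam2d = {}
    for name, ax in (
        ("Maximum2DDiameterSlice", 2),
        ("Maximum2DDiameterColumn", 1),
        ("Maximum2DDiameterRow", 0),
    ):
        best = 0.0
        for plane in np.unique(bnd[:, ax]):
            pts = phys[bnd[:, ax] == plane][:, [a for a in range(3) if a != ax]]
            best = max(best, _max_pairwise(pts))
        diam2d[name] = best

    # axis lengths: eigenvalues of the physical-coordinate covariance
    coords = np.argwhere(fg) * np.asarray(sp)
    if len(coords) < 2:
        warnings.warn("single-voxel mask: PCA axis lengths degenerate, reported as 0", stacklevel=2)
        eig = np.zeros(3)
    else:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)

    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    out = {
        "MeshVolume": mesh_v,
        "VoxelVolume": voxel_v,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_v if mesh_v > 0 else 0.0,
        "Sphericity": (36.0 * np.pi * mesh_v**2) ** (1.0 / 3.0) / area if area > 0 else 0.0,
        "Maximum3DDiameter": d3,
        **diam2d,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
    return out
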