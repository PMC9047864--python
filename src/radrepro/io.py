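"""Reading and writing volumes/masks as NRRD or NIfTI, via SimpleITK.

The in-memory convention is array axis ``i`` = physical axis ``i`` with
``spacing[i]`` mm per voxel (SimpleITK's reversed array order is handled
internally), so a volume written to ``.nrrd`` and re-read — or written to
``.nii.gz`` instead — comes back with an identical array, spacing and
origin.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import ImageVolume, RoiMask

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

_KNOWN_EXT = (".nrrd", ".nii", ".nii.gz", ".mha")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _KNOWN_EXT):
        raise ValueError(f"unsupported volume format for {path.name}; use one of {_KNOWN_EXT}")


def _to_sitk(array: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_image(path, image: ImageVolume) -> Path:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(image.array.astype(np.float32), image.spacing, image.origin),
                    str(path), useCompression=True)
    return path


def read_image(path) -> ImageVolume:
    path = Path(path)
    _check_ext(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ImageVolume(arr.astype(np.float64), spacing, origin)


def write_mask(path, mask: RoiMask) -> Path:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(mask.array.astype(np.uint8), mask.spacing, mask.origin),
                    str(path), useCompression=True)
    return path


def read_mask(path) -> RoiMask:
    path = Path(path)
    _check_ext(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    bad = np.setdiff1d(np.unique(arr), [0, 1])
    if bad.size:
        raise ValueError(f"mask file {path.name} is not binary: found value {bad[0]!r}")
    return RoiMask(arr.astype(np.uint8), spacing, origin)
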