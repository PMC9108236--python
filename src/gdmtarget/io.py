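"""Reading and writing images, masks and transforms.

Images and masks are stored as NRRD or NIfTI-1 (chosen by file extension)
through SimpleITK, with spacing and origin preserved; masks are written as
unsigned 8-bit 0/1 volumes.  Rigid transforms travel as small JSON files::

    {"translation_mm": [x, y, z], "rotation_deg": [rz, ry, rx],
     "center_mm": [x, y, z], "fixed": "<series id>", "moving": "<series id>"}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import BinaryStructure, ImageVolume, RigidTransform

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_transform",
    "write_transform",
]

_KNOWN_EXT = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not name.endswith(_KNOWN_EXT):
        raise ValueError(
            f"unsupported image format {path.name!r}; use one of {_KNOWN_EXT}"
        )


def read_image(path: str | Path, series_id: str | None = None) -> ImageVolume:
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    return ImageVolume.from_sitk(img, series_id or path.stem)


def write_image(volume: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path))


def read_mask(path: str | Path, label: str | None = None) -> BinaryStructure:
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    vol = ImageVolume.from_sitk(img)
    arr = vol.data
    bad = np.setdiff1d(np.unique(arr), [0.0, 1.0])
    if bad.size:
        raise ValueError(
            f"{path.name}: mask file must contain only 0/1 voxels, found {bad.tolist()}"
        )
    return BinaryStructure(arr > 0.5, vol.grid, label or path.stem)


def write_mask(structure: BinaryStructure, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(structure.mask.astype(np.uint8).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(structure.grid.spacing))
    img.SetOrigin(tuple(structure.grid.origin))
    sitk.WriteImage(img, str(path))


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "translation_mm": list(transform.translation),
        "rotation_deg": list(transform.rotation_deg),
        "center_mm": list(transform.center),
        "fixed": transform.fixed_frame,
        "moving": transform.moving_frame,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_transform(path: str | Path) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    return RigidTransform(
        translation=tuple(data["translation_mm"]),
        rotation_deg=tuple(data["rotation_deg"]),
        center=tuple(data.get("center_mm", (0.0, 0.0, 0.0))),
        fixed_frame=data.get("fixed", ""),
        moving_frame=data.get("moving", ""),
    )
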