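"""Core data model: image volumes, binary structures, rigid transforms.

Coordinate convention
---------------------
Arrays are indexed ``data[i, j, k]`` where axis 0 is x (+x = patient Left),
axis 1 is y (+y = Posterior) and axis 2 is z (+z = Superior) — the DICOM LPS
patient frame.  The physical position of voxel ``(i, j, k)`` is
``origin + spacing * (i, j, k)`` in millimetres.

Transforms follow the resampling convention: a :class:`RigidTransform`
attached to a secondary (moving) series maps a point expressed in the
primary (fixed) frame to the location of the same anatomy in the secondary
series.  Its translation therefore reads as the anatomy's displacement in
the secondary series relative to the primary — the quantity a planning
system reports after registration, and the one the margin construction
consumes directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "ImageVolume",
    "BinaryStructure",
    "RigidTransform",
    "DeformationVector",
    "AnatomicalMargin",
    "StudySet",
    "resample_to_reference",
    "volume_cm3",
    "translate_structure",
]


@dataclass(frozen=True)
class Grid:
    """Sampling lattice shared by an image volume and its structures."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm position(s) of fractional voxel index/indices (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) physical corners of the voxel-centre bounding box."""
        low = np.asarray(self.origin, dtype=float)
        high = low + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return low, high


@dataclass
class ImageVolume:
    """A CT-like scalar volume on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid
    series_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 3-D, got ndim={self.data.ndim}")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        series_id: str = "",
    ) -> "ImageVolume":
        data = np.asarray(data)
        return cls(data, Grid(data.shape, spacing, origin), series_id)

    def to_sitk(self) -> sitk.Image:
        # SimpleITK indexes arrays [z, y, x]; our arrays are [x, y, z].
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.grid.spacing))
        img.SetOrigin(tuple(self.grid.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, series_id: str = "") -> "ImageVolume":
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise ValueError(
                "only identity-direction (axis-aligned LPS) images are supported; "
                f"got direction {direction.tolist()}"
            )
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls.from_array(data, img.GetSpacing(), img.GetOrigin(), series_id)


@dataclass
class BinaryStructure:
    """A boolean mask (CTV, ITV, PTV or ROI) living on a reference grid."""

    mask: np.ndarray
    grid: Grid
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()

    def same_grid(self, other: "BinaryStructure") -> bool:
        return self.grid == other.grid

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the true voxels."""
        if self.is_empty():
            raise ValueError(f"structure {self.label!r} is empty; no centroid")
        idx = np.argwhere(self.mask).mean(axis=0)
        return self.grid.index_to_physical(idx)

    def with_mask(self, mask: np.ndarray, label: str | None = None) -> "BinaryStructure":
        return BinaryStructure(mask, self.grid, self.label if label is None else label)


def require_same_grid(a: BinaryStructure, b: BinaryStructure) -> None:
    """Refuse to compare structures living on different grids.

    Silent comparison across grids is exactly the misregistration the
    workflow exists to avoid; resample explicitly first.
    """
    if not a.same_grid(b):
        raise ValueError(
            f"structures {a.label!r} and {b.label!r} live on different grids "
            f"({a.grid} vs {b.grid}); resample to a common grid first"
        )


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: 3 translations (mm) + 3 Euler rotations (deg).

    Maps a point in the fixed (primary) frame to the corresponding
    anatomical location in the moving (secondary) series::

        p_moving = R @ (p_fixed - center) + center + translation

    ``rotation_deg`` are intrinsic Z-Y-X Euler angles ``(rz, ry, rx)``;
    ``center`` is the rotation centre in mm (the registration ROI centroid).
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fixed_frame: str = ""
    moving_frame: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float)
        r = np.asarray(self.rotation_deg, dtype=float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("transform parameters must be finite")
        if np.any(r <= -180.0) or np.any(r > 180.0):
            raise ValueError(f"rotations must lie in (-180, 180], got {tuple(r)}")
        object.__setattr__(self, "translation", tuple(map(float, t)))
        object.__setattr__(self, "rotation_deg", tuple(map(float, r)))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def is_identity(self) -> bool:
        return not (any(self.translation) or any(self.rotation_deg))

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-frame point(s) (..., 3) into the moving series."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        return (p - c) @ self.rotation_matrix().T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix()
        # p_f = R^T (p_m - c - t) + c  =  R^T (p_m - c) + c - R^T t
        rz, ry, rx = Rotation.from_matrix(R.T).as_euler("ZYX", degrees=True)
        t_inv = -(R.T @ np.asarray(self.translation))
        return RigidTransform(
            tuple(t_inv),
            (rz, ry, rx),
            self.center,
            fixed_frame=self.moving_frame,
            moving_frame=self.fixed_frame,
        )

    def with_translation(self, t: np.ndarray) -> "RigidTransform":
        return replace(self, translation=tuple(np.asarray(t, dtype=float)))

    def to_sitk(self) -> sitk.Transform:
        tf = sitk.Euler3DTransform()
        tf.SetCenter(tuple(self.center))
        tf.SetMatrix(tuple(self.rotation_matrix().ravel()))
        tf.SetTranslation(tuple(self.translation))
        return tf

    @classmethod
    def identity(cls, fixed_frame: str = "", moving_frame: str = "") -> "RigidTransform":
        return cls(fixed_frame=fixed_frame, moving_frame=moving_frame)


@dataclass(frozen=True)
class DeformationVector:
    """Marker–target geometry change for one secondary series.

    ``d`` (mm, LPS) is the translation of the reference-structure
    registration minus the translation of the marker registration: the
    displacement of the target surrogate relative to the tracked marker in
    that respiratory phase.  Zero when marker and target move together.
    """

    series_id: str
    d: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.d, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError(f"deformation vector must be 3 finite floats, got {self.d}")
        object.__setattr__(self, "d", tuple(map(float, v)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.d, dtype=float)


@dataclass(frozen=True)
class AnatomicalMargin:
    """Six non-negative expansion distances in mm (the GDM).

    Directions follow the LPS frame: left = +x, right = −x, posterior = +y,
    anterior = −y, superior = +z, inferior = −z.
    """

    anterior: float = 0.0
    posterior: float = 0.0
    right: float = 0.0
    left: float = 0.0
    superior: float = 0.0
    inferior: float = 0.0

    def __post_init__(self) -> None:
        for name in ("anterior", "posterior", "right", "left", "superior", "inferior"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"margin {name} must be finite and >= 0, got {v}")
            object.__setattr__(self, name, v)

    @property
    def is_zero(self) -> bool:
        return all(
            getattr(self, n) == 0.0
            for n in ("anterior", "posterior", "right", "left", "superior", "inferior")
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "A": self.anterior,
            "P": self.posterior,
            "R": self.right,
            "L": self.left,
            "S": self.superior,
            "I": self.inferior,
        }

    def low_high_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-axis (negative-direction, positive-direction) extents in mm.

        Axis order x, y, z; negative x is Right, positive x Left, etc.
        """
        low = np.array([self.right, self.anterior, self.inferior])
        high = np.array([self.left, self.posterior, self.superior])
        return low, high


@dataclass
class StudySet:
    """One planning-CT study: primary breath-hold series plus motion-sampling
    secondaries, the CTV, and the registration ROIs."""

    primary: ImageVolume
    secondaries: list[ImageVolume]
    ctv: BinaryStructure
    spine_roi: BinaryStructure
    marker_roi: BinaryStructure
    ref_roi: BinaryStructure

    def __post_init__(self) -> None:
        if len(self.secondaries) < 1:
            raise ValueError("a study needs at least one secondary series")
        if self.ctv.is_empty():
            raise ValueError("CTV must be non-empty")
        rois = [self.spine_roi, self.marker_roi, self.ref_roi]
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                if np.any(rois[i].mask & rois[j].mask):
                    raise ValueError(
                        f"ROIs {rois[i].label!r} and {rois[j].label!r} overlap"
                    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_overlap(moving_grid: Grid, reference_grid: Grid, transform: RigidTransform) -> None:
    lo, hi = reference_grid.extent_mm()
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    mapped = transform.apply(corners)
    mlo, mhi = moving_grid.extent_mm()
    if np.any(mapped.max(axis=0) < mlo) or np.any(mapped.min(axis=0) > mhi):
        raise ValueError(
            "reference grid does not overlap the moving volume after transform: "
            f"reference extent {lo.tolist()}..{hi.tolist()} mm maps to "
            f"{mapped.min(axis=0).tolist()}..{mapped.max(axis=0).tolist()} mm, "
            f"moving extent {mlo.tolist()}..{mhi.tolist()} mm"
        )


def resample_to_reference(
    moving: ImageVolume | BinaryStructure,
    reference_grid: Grid,
    transform: RigidTransform,
):
    """Resample a volume or mask onto ``reference_grid`` under ``transform``.

    ``transform`` maps reference-frame points into the moving series
    (resampling convention).  Scalar images use trilinear interpolation;
    masks use nearest-neighbour so they stay boolean.  The identity
    transform on an identical grid is a bit-exact no-op.
    """
    is_mask = isinstance(moving, BinaryStructure)
    grid = moving.grid
    if transform.is_identity and grid == reference_grid:
        if is_mask:
            return BinaryStructure(moving.mask.copy(), reference_grid, moving.label)
        return ImageVolume(moving.data.copy(), reference_grid, moving.series_id)

    _check_overlap(grid, reference_grid, transform)

    if is_mask:
        src = ImageVolume(moving.mask.astype(np.float32), grid)
        interp = sitk.sitkNearestNeighbor
        default = 0.0
    else:
        src = moving
        interp = sitk.sitkLinear
        default = float(moving.data.min())

    ref_img = sitk.Image([int(n) for n in reference_grid.shape], sitk.sitkFloat32)
    ref_img.SetSpacing(tuple(reference_grid.spacing))
    ref_img.SetOrigin(tuple(reference_grid.origin))
    out = sitk.Resample(src.to_sitk(), ref_img, transform.to_sitk(), interp, default)
    arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    if is_mask:
        return BinaryStructure(arr > 0.5, reference_grid, moving.label)
    return ImageVolume(arr, reference_grid, moving.series_id)


def volume_cm3(s: BinaryStructure) -> float:
    """Structure volume in cm³ (true-voxel count × voxel volume)."""
    return s.voxel_count * s.grid.voxel_volume_mm3 / 1000.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (platform-independent)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(int)


def translate_structure(s: BinaryStructure, d) -> BinaryStructure:
    """Shift a mask by ``d`` mm, rounded to the nearest whole-voxel offset.

    Voxels pushed outside the grid are dropped with a warning; a shift at
    least as large as the grid extent is an error.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (3,) or not np.all(np.isfinite(d)):
        raise ValueError(f"translation must be 3 finite floats, got {d}")
    shift = _round_half_away(d / np.asarray(s.grid.spacing))
    shape = np.asarray(s.grid.shape)
    if np.any(np.abs(shift) >= shape):
        raise ValueError(
            f"voxel shift {shift.tolist()} exceeds grid extent {shape.tolist()}"
        )
    out = np.zeros_like(s.mask)
    src = []
    dst = []
    for ax in range(3):
        k = int(shift[ax])
        n = int(shape[ax])
        if k >= 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    out[tuple(dst)] = s.mask[tuple(src)]
    lost = s.voxel_count - int(out.sum())
    if lost:
        logger.warning(
            "translate_structure(%r, %s): %d voxel(s) shifted outside the grid",
            s.label, d.tolist(), lost,
        )
    return s.with_mask(out)
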