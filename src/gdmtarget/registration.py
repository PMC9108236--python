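"""The triple registration chain.

Every motion-sampling secondary series is registered to the primary
breath-hold series three times, each step refining the previous one:

1. ``register_spine_6d`` — 6-DOF rigid alignment on a spine ROI (the
   motion-intact anatomy used for patient setup), mean-squared intensity
   difference, multi-resolution gradient-free (Powell) optimisation.
2. ``register_translation_marker`` — translation-only alignment of the
   tracked marker, closed-form matching of intensity-weighted marker
   centroids: robust to metal artefacts and exactly reproducible.
3. ``register_translation_local`` — translation-only alignment of the
   local reference structure (LMCA-like heterogeneity) by maximising
   normalised cross-correlation over a deterministic translation search.

Rotations are estimated once, at the spine step, and frozen afterwards —
single-marker tracking can only correct translations, so the chain mirrors
the clinical setup.  The difference between the translations of steps 3
and 2 is the marker–target deformation vector for that series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import (
    BinaryStructure,
    DeformationVector,
    ImageVolume,
    RigidTransform,
    StudySet,
    resample_to_reference,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationResult",
    "ChainResult",
    "detect_marker",
    "register_spine_6d",
    "register_translation_marker",
    "register_translation_local",
    "deformation_vector",
    "run_chain",
]

DEFAULT_MARKER_HU = 1500.0  # metal vs bone separation
SPINE_ROTATION_CAPTURE_DEG = 10.0
SPINE_TRANSLATION_CAPTURE_MM = 40.0
LOCAL_SEARCH_MM = 10.0


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one registration step."""

    transform: RigidTransform
    metric_value: float
    roi_label: str
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.metric_value):
            raise ValueError("metric value must be finite")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class ChainResult:
    """All three steps for one secondary series plus the deformation vector."""

    series_id: str
    spine: RegistrationResult
    marker: RegistrationResult
    ref: RegistrationResult
    deformation: DeformationVector


def detect_marker(
    image: ImageVolume,
    search_roi: BinaryStructure,
    hu_threshold: float = DEFAULT_MARKER_HU,
) -> np.ndarray:
    """Locate the marker: intensity-weighted centroid (mm) of the largest
    connected above-threshold component inside the ROI."""
    if search_roi.is_empty():
        raise ValueError("marker search ROI is empty")
    if image.grid != search_roi.grid:
        raise ValueError("marker ROI must live on the image grid")
    bright = (image.data > hu_threshold) & search_roi.mask
    if not bright.any():
        raise ValueError(
            f"marker not found: no voxel above {hu_threshold} HU inside ROI "
            f"{search_roi.label!r}"
        )
    labels, n = ndimage.label(bright)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    component = labels == counts.argmax()
    w = image.data[component] - hu_threshold  # weight by excess intensity
    idx = np.argwhere(component).astype(float)
    centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    return image.grid.index_to_physical(centroid_idx)


def _roi_centroid(roi: BinaryStructure) -> np.ndarray:
    return roi.centroid_mm()


def register_spine_6d(
    fixed: ImageVolume,
    moving: ImageVolume,
    spine_roi: BinaryStructure,
    max_iterations: int = 60,
) -> RegistrationResult:
    """6-DOF rigid spine registration (mean squares, multi-resolution Powell).

    Capture range is ±10° / ±40 mm; results outside it are flagged as
    non-converged with a warning rather than rejected.
    """
    if spine_roi.is_empty():
        raise ValueError("spine ROI is empty")
    center = _roi_centroid(spine_roi)

    # metric cost scales with the fixed-image sample count, so restrict the
    # fixed image to the ROI bounding box (small pad for gradient support);
    # the moving image stays full to keep the capture range.
    idx = np.argwhere(spine_roi.mask)
    pad = 4
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad, np.asarray(fixed.grid.shape) - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    crop_origin = fixed.grid.index_to_physical(lo)
    f_crop = ImageVolume.from_array(
        fixed.data[sl], fixed.grid.spacing, tuple(crop_origin), fixed.series_id
    )

    f_img = f_crop.to_sitk()
    m_img = moving.to_sitk()
    mask_img = sitk.GetImageFromArray(
        np.ascontiguousarray(spine_roi.mask[sl].astype(np.uint8).transpose(2, 1, 0))
    )
    mask_img.CopyInformation(f_img)

    initial = sitk.Euler3DTransform()
    initial.SetCenter(tuple(center))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsPowell(
        numberOfIterations=max_iterations,
        maximumLineIterations=25,
        stepLength=4.0,
        stepTolerance=1e-4,
        valueTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)

    reg.Execute(f_img, m_img)
    metric = float(reg.GetMetricValue())
    iterations = max(1, int(reg.GetOptimizerIteration()))

    matrix = np.asarray(initial.GetMatrix()).reshape(3, 3)
    rz, ry, rx = Rotation.from_matrix(matrix).as_euler("ZYX", degrees=True)
    transform = RigidTransform(
        translation=tuple(initial.GetTranslation()),
        rotation_deg=(rz, ry, rx),
        center=tuple(initial.GetCenter()),
        fixed_frame=fixed.series_id,
        moving_frame=moving.series_id,
    )
    converged = bool(
        np.all(np.abs(transform.translation) <= SPINE_TRANSLATION_CAPTURE_MM)
        and np.all(np.abs(transform.rotation_deg) <= SPINE_ROTATION_CAPTURE_DEG)
    )
    if not converged:
        logger.warning(
            "spine registration of %r left the capture range (t=%s mm, r=%s deg)",
            moving.series_id, transform.translation, transform.rotation_deg,
        )
    return RegistrationResult(transform, metric, spine_roi.label, iterations, converged)


def register_translation_marker(
    fixed: ImageVolume,
    moving: ImageVolume,
    roi: BinaryStructure,
    prior: RigidTransform,
    hu_threshold: float = DEFAULT_MARKER_HU,
) -> RegistrationResult:
    """Translation-only marker alignment on top of the spine result.

    Closed form: the moving series is resampled under the prior, both
    marker centroids are detected, and the translation is updated so the
    transform maps the fixed marker exactly onto the moving one.  Rotations
    (and rotation centre) are copied unchanged from the prior.
    """
    m_fixed = detect_marker(fixed, roi, hu_threshold)
    resampled = resample_to_reference(moving, fixed.grid, prior)
    m_resampled = detect_marker(resampled, roi, hu_threshold)
    # marker appears at m_resampled = position offset by the residual motion;
    # adding (m_resampled - m_fixed) to the translation maps fixed onto moving.
    incr = m_resampled - m_fixed
    transform = prior.with_translation(np.asarray(prior.translation) + incr)
    metric = float(np.linalg.norm(incr))
    return RegistrationResult(transform, metric, roi.label, 1)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def register_translation_local(
    fixed: ImageVolume,
    moving: ImageVolume,
    roi: BinaryStructure,
    prior: RigidTransform,
    search_mm: float = LOCAL_SEARCH_MM,
    fine_step_mm: float = 0.25,
) -> RegistrationResult:
    """Translation-only alignment to the local reference structure.

    Maximises normalised cross-correlation of intensities within the ROI
    over a deterministic search: whole-voxel offsets spanning ±``search_mm``,
    a ±1-voxel grid at ``fine_step_mm`` around the best coarse offset, and a
    final per-axis parabolic refinement.  No random restarts, so repeated
    runs are identical.  Rotations are copied unchanged from the prior.
    """
    if roi.is_empty():
        raise ValueError("reference-structure ROI is empty")
    if fixed.grid != roi.grid:
        raise ValueError("reference ROI must live on the fixed grid")
    f_vals = fixed.data[roi.mask].astype(np.float64)
    if f_vals.std() == 0:
        raise ValueError(
            "reference structure not discriminable: ROI intensity is flat"
        )
    resampled = resample_to_reference(moving, fixed.grid, prior)
    m_data = resampled.data.astype(np.float64)

    roi_idx = np.argwhere(roi.mask).astype(np.float64).T  # (3, n)
    spacing = np.asarray(fixed.grid.spacing)
    Rinv = prior.rotation_matrix().T

    def score(u_mm: np.ndarray) -> float:
        # extra moving->fixed displacement u shifts resampled content by
        # +R^{-1} u in the fixed frame; sample it back at roi + R^{-1} u
        shift_vox = (Rinv @ u_mm) / spacing
        pts = roi_idx + shift_vox[:, None]
        vals = ndimage.map_coordinates(m_data, pts, order=1, mode="nearest")
        return _ncc(f_vals, vals)

    coarse = [
        np.arange(-np.floor(search_mm / s), np.floor(search_mm / s) + 1) * s
        for s in spacing
    ]
    best_u = np.zeros(3)
    best = -np.inf
    for ux in coarse[0]:
        for uy in coarse[1]:
            for uz in coarse[2]:
                u = np.array([ux, uy, uz])
                v = score(u)
                if v > best:
                    best, best_u = v, u

    # fine grid ±1 voxel around the coarse optimum
    fine_axes = [
        best_u[i] + np.arange(-spacing[i], spacing[i] + fine_step_mm / 2, fine_step_mm)
        for i in range(3)
    ]
    for ux in fine_axes[0]:
        for uy in fine_axes[1]:
            for uz in fine_axes[2]:
                u = np.array([ux, uy, uz])
                v = score(u)
                if v > best:
                    best, best_u = v, u

    # per-axis parabolic refinement on the fine step
    refined = best_u.copy()
    for ax in range(3):
        h = fine_step_mm
        u_minus, u_plus = refined.copy(), refined.copy()
        u_minus[ax] -= h
        u_plus[ax] += h
        f0, fm, fp = score(refined), score(u_minus), score(u_plus)
        denom = fm - 2 * f0 + fp
        if denom < 0:  # proper maximum
            delta = 0.5 * h * (fm - fp) / denom
            refined[ax] += float(np.clip(delta, -h, h))
    v_refined = score(refined)
    if v_refined > best:  # strictly better only, so exact optima stay exact
        best_u = refined
        best = v_refined

    transform = prior.with_translation(np.asarray(prior.translation) + best_u)
    return RegistrationResult(transform, best, roi.label, 1)


def deformation_vector(
    marker_result: RegistrationResult, ref_result: RegistrationResult
) -> DeformationVector:
    """Marker–target geometry change: translation(ref) − translation(marker)."""
    if marker_result.transform.moving_frame != ref_result.transform.moving_frame:
        raise ValueError(
            "registration results refer to different secondary series: "
            f"{marker_result.transform.moving_frame!r} vs "
            f"{ref_result.transform.moving_frame!r}"
        )
    d = np.asarray(ref_result.transform.translation) - np.asarray(
        marker_result.transform.translation
    )
    return DeformationVector(marker_result.transform.moving_frame, tuple(d))


def run_chain(
    fixed: ImageVolume,
    moving: ImageVolume,
    spine_roi: BinaryStructure,
    marker_roi: BinaryStructure,
    ref_roi: BinaryStructure,
    hu_threshold: float = DEFAULT_MARKER_HU,
) -> ChainResult:
    """Execute the full 6D/spine + 3D/marker + 3D/RefSTRUCT chain."""
    spine = register_spine_6d(fixed, moving, spine_roi)
    marker = register_translation_marker(
        fixed, moving, marker_roi, spine.transform, hu_threshold
    )
    ref = register_translation_local(fixed, moving, ref_roi, marker.transform)
    return ChainResult(
        series_id=moving.series_id,
        spine=spine,
        marker=marker,
        ref=ref,
        deformation=deformation_vector(marker, ref),
    )


def run_study(study: StudySet, hu_threshold: float = DEFAULT_MARKER_HU) -> list[ChainResult]:
    """Register every secondary series of a study to its primary."""
    return [
        run_chain(
            study.primary, sec, study.spine_roi, study.marker_roi, study.ref_roi,
            hu_threshold,
        )
        for sec in study.secondaries
    ]
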