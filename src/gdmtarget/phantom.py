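"""Synthetic respiratory thorax phantom with exported ground truth.

The phantom emulates the planning-CT study the workflow consumes: an
expiration breath-hold primary series, an inspiration series and several
free-breathing series, rendered on a common grid in HU-like units.  It
contains a soft-tissue body, a rigid spine (moves only with the body), a
heart blood pool that shifts with the respiratory phase, a metal marker
(ICD-lead-tip analogue) and a contrast heterogeneity (LMCA-region
analogue, "RefSTRUCT") inside the heart, each with its own additional
phase-dependent offset, and a spherical target (CTV) near the reference
structure.  Because the marker offset δ_m(φ) and reference-structure
offset δ_r(φ) are independently programmable, the marker–target geometry
deformation the workflow measures is a first-class simulated quantity with
exact ground truth.

Surfaces are rendered with a ~1-voxel smoothstep edge so that sub-voxel
translations produce the sub-voxel intensity shifts real CT data shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    BinaryStructure,
    DeformationVector,
    Grid,
    ImageVolume,
    RigidTransform,
    StudySet,
    translate_structure,
)

__all__ = [
    "PhaseMotion",
    "PhantomSpec",
    "GroundTruth",
    "default_breathing_profile",
    "generate_series",
]

# HU-like palette
HU_AIR = -1000.0
HU_SOFT = 40.0
HU_HEART = 300.0
HU_SPINE = 700.0
HU_MARKER = 3000.0
HU_REFSTRUCT = HU_HEART + 150.0


@dataclass(frozen=True)
class PhaseMotion:
    """Programmed motion of one secondary phase, all in mm / deg.

    ``body_shift``/``body_rot_deg`` move the whole patient (spine included);
    ``heart_shift`` moves the heart and everything inside it relative to the
    spine; ``marker_offset`` (δ_m) and ``refstruct_offset`` (δ_r) add
    independent offsets of marker and reference structure relative to the
    heart.  The target moves with the reference structure.
    """

    phase: str
    body_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    heart_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    marker_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    refstruct_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class PhantomSpec:
    """Geometry, intensities, motion and noise of one phantom study.

    Defaults give a 96³ grid at 1.5 mm isotropic spacing (144 mm cube) with
    anatomy proportions loosely matching a thorax cross-section: posterior
    spine, left-of-centre heart, marker and reference structure well
    separated inside the heart.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    body_center: tuple[float, float, float] = (71.0, 71.0, 71.0)
    body_semiaxes: tuple[float, float, float] = (64.0, 52.0, 70.0)
    spine_center_xy: tuple[float, float] = (71.0, 108.0)
    spine_radius: float = 10.0

    heart_center: tuple[float, float, float] = (59.0, 59.0, 71.0)
    heart_semiaxes: tuple[float, float, float] = (33.0, 29.0, 35.0)

    marker_offset0: tuple[float, float, float] = (12.0, -6.0, -14.0)
    marker_radius: float = 2.5
    refstruct_offset0: tuple[float, float, float] = (-10.0, 4.0, 16.0)
    refstruct_radius: float = 4.5
    ctv_offset0: tuple[float, float, float] = (-14.0, 10.0, -8.0)
    ctv_radius: float = 9.0

    motions: list[PhaseMotion] = field(default_factory=list)
    noise_sd_hu: float = 20.0
    edge_mm: float = 1.5
    streak_artifacts: bool = False  # radial bright spokes around the marker
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motions:
            self.motions = default_breathing_profile(4, 8.0, self.seed)

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)

    def marker_center0(self) -> np.ndarray:
        return np.asarray(self.heart_center) + np.asarray(self.marker_offset0)

    def refstruct_center0(self) -> np.ndarray:
        return np.asarray(self.heart_center) + np.asarray(self.refstruct_offset0)

    def ctv_center0(self) -> np.ndarray:
        return np.asarray(self.heart_center) + np.asarray(self.ctv_offset0)


@dataclass
class GroundTruth:
    """Exact programmed quantities the registration chain is meant to recover."""

    body_transforms: dict[str, RigidTransform]
    marker_net_mm: dict[str, np.ndarray]
    refstruct_net_mm: dict[str, np.ndarray]
    deformations: dict[str, DeformationVector]

    def true_deformation_vectors(self) -> list[DeformationVector]:
        return [self.deformations[k] for k in sorted(self.deformations)]

    def true_ctv(self, ctv: BinaryStructure, phase: str) -> BinaryStructure:
        """Target position in the tracked marker's dynamic frame for one phase."""
        out = translate_structure(ctv, self.deformations[phase].as_array())
        out.label = f"CTV@{phase}"
        return out

    def as_dict(self) -> dict:
        return {
            "deformations_mm": {
                k: list(v.d) for k, v in sorted(self.deformations.items())
            },
            "marker_net_mm": {k: v.tolist() for k, v in sorted(self.marker_net_mm.items())},
            "refstruct_net_mm": {
                k: v.tolist() for k, v in sorted(self.refstruct_net_mm.items())
            },
            "body_transforms": {
                k: {
                    "translation_mm": list(t.translation),
                    "rotation_deg": list(t.rotation_deg),
                    "center_mm": list(t.center),
                }
                for k, t in sorted(self.body_transforms.items())
            },
        }


def default_breathing_profile(
    n_phases: int, amplitude_mm: float, seed: int = 0
) -> list[PhaseMotion]:
    """Inspiration plus ``n_phases - 1`` free-breathing phases.

    Heart motion is superior–inferior dominant with smaller A-P/L-R
    components.  The inspiration phase sits deterministically at the
    amplitude extreme (inferior heart displacement of exactly
    ``amplitude_mm``, reflecting that instructed inspiration tends to
    exaggerate the free-breathing range); free-breathing phases are drawn
    uniformly within ±amplitude on the SI axis (±0.3 amplitude on A-P/L-R),
    reproducibly under ``seed``.  Marker and reference-structure offsets
    scale with the heart excursion, the reference structure moving slightly
    more — a mild marker–target deformation in every phase.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if n_phases < 1:
        raise ValueError("need at least one phase (inspiration)")
    a = float(amplitude_mm)
    motions = [
        PhaseMotion(
            phase="ibh",
            body_shift=(0.0, 0.25 * a, -0.5 * a),
            heart_shift=(0.15 * a, -0.2 * a, -a),
            marker_offset=(0.05 * a, 0.0, -0.1 * a),
            refstruct_offset=(-0.05 * a, 0.1 * a, -0.35 * a),
        )
    ]
    rng = np.random.default_rng(seed)
    for i in range(1, n_phases):
        si = rng.uniform(-a, a)
        ap = rng.uniform(-0.3 * a, 0.3 * a)
        lr = rng.uniform(-0.3 * a, 0.3 * a)
        frac = si / a if a > 0 else 0.0
        motions.append(
            PhaseMotion(
                phase=f"fb{i}",
                body_shift=tuple(rng.uniform(-0.15 * a, 0.15 * a, size=3)),
                heart_shift=(lr, ap, si),
                marker_offset=(0.04 * a * frac, -0.02 * a * frac, -0.08 * a * frac),
                refstruct_offset=(-0.04 * a * frac, 0.08 * a * frac, -0.3 * a * frac),
            )
        )
    return motions


def _smooth_ball(dist_mm: np.ndarray, radius: float, edge: float) -> np.ndarray:
    """Occupancy in [0, 1] with a linear edge of width ``edge`` mm."""
    return np.clip((radius + edge / 2.0 - dist_mm) / edge, 0.0, 1.0)


def _paint(img: np.ndarray, weight: np.ndarray, value: float) -> None:
    img *= 1.0 - weight
    img += value * weight


class _Renderer:
    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        grid = spec.grid
        ax = [
            np.asarray(grid.origin)[i] + np.arange(grid.shape[i]) * grid.spacing[i]
            for i in range(3)
        ]
        self.X = ax[0][:, None, None]
        self.Y = ax[1][None, :, None]
        self.Z = ax[2][None, None, :]
        self.edge = spec.edge_mm

    def _pts_rel(self, center: np.ndarray, rot: Rotation | None, pivot: np.ndarray):
        """Coordinates relative to a structure placed at ``center`` after an
        optional whole-body rotation about ``pivot``."""
        if rot is None:
            return self.X - center[0], self.Y - center[1], self.Z - center[2]
        # structure occupies {R(p0 - pivot) + pivot}; invert per voxel:
        # q = R^T (p - pivot) + pivot - center
        Rm = rot.as_matrix()
        px = self.X - pivot[0]
        py = self.Y - pivot[1]
        pz = self.Z - pivot[2]
        qx = Rm[0, 0] * px + Rm[1, 0] * py + Rm[2, 0] * pz + pivot[0] - center[0]
        qy = Rm[0, 1] * px + Rm[1, 1] * py + Rm[2, 1] * pz + pivot[1] - center[1]
        qz = Rm[0, 2] * px + Rm[1, 2] * py + Rm[2, 2] * pz + pivot[2] - center[2]
        return qx, qy, qz

    def _ellipsoid_dist(self, center, semiaxes, rot, pivot):
        dx, dy, dz = self._pts_rel(np.asarray(center), rot, pivot)
        a = np.asarray(semiaxes, dtype=float)
        rho = np.sqrt((dx / a[0]) ** 2 + (dy / a[1]) ** 2 + (dz / a[2]) ** 2)
        return (rho - 1.0) * a.min()  # approximate signed mm distance

    def _sphere_dist(self, center, rot, pivot):
        dx, dy, dz = self._pts_rel(np.asarray(center), rot, pivot)
        return np.sqrt(dx**2 + dy**2 + dz**2)

    _STREAK_HU = 1800.0
    _STREAK_START_MM = 5.0
    _STREAK_END_MM = 18.0
    _STREAK_RADIUS_MM = 0.8

    def _paint_streaks(self, img, marker_c, rot, pivot) -> None:
        # six thin bright spokes in the axial plane, detached from the marker
        # ball so they form separate small components: a stress test for the
        # largest-component rule in marker detection
        dx, dy, dz = self._pts_rel(np.asarray(marker_c), rot, pivot)
        for angle in np.deg2rad(np.arange(0, 360, 60)):
            ux, uy = np.cos(angle), np.sin(angle)
            t = np.clip(dx * ux + dy * uy, self._STREAK_START_MM, self._STREAK_END_MM)
            dist = np.sqrt((dx - t * ux) ** 2 + (dy - t * uy) ** 2 + dz**2)
            _paint(img, _smooth_ball(dist, self._STREAK_RADIUS_MM, self.edge),
                   self._STREAK_HU)

    def render(self, motion: PhaseMotion | None, rng: np.random.Generator | None) -> np.ndarray:
        s = self.spec
        if motion is None:
            motion = PhaseMotion(phase="ebh")
        body_shift = np.asarray(motion.body_shift)
        heart_shift = np.asarray(motion.heart_shift)
        rot = (
            Rotation.from_euler("ZYX", motion.body_rot_deg[::-1], degrees=True)
            if any(motion.body_rot_deg)
            else None
        )
        pivot = np.asarray(s.body_center)

        img = np.full(s.shape, HU_AIR, dtype=np.float64)

        body_c = np.asarray(s.body_center) + body_shift
        d = self._ellipsoid_dist(body_c, s.body_semiaxes, rot, pivot + body_shift)
        _paint(img, _smooth_ball(d, 0.0, self.edge), HU_SOFT)

        # spine: cylinder along z, rigid with the body
        spine_c = np.array([s.spine_center_xy[0], s.spine_center_xy[1], s.body_center[2]])
        spine_c = spine_c + body_shift
        dx, dy, _ = self._pts_rel(spine_c, rot, pivot + body_shift)
        rad = np.sqrt(dx**2 + dy**2)
        _paint(img, _smooth_ball(rad, s.spine_radius, self.edge), HU_SPINE)

        heart_c = np.asarray(s.heart_center) + body_shift + heart_shift
        d = self._ellipsoid_dist(heart_c, s.heart_semiaxes, rot, pivot + body_shift)
        _paint(img, _smooth_ball(d, 0.0, self.edge), HU_HEART)

        ref_c = (
            np.asarray(s.heart_center)
            + np.asarray(s.refstruct_offset0)
            + body_shift
            + heart_shift
            + np.asarray(motion.refstruct_offset)
        )
        d = self._sphere_dist(ref_c, rot, pivot + body_shift)
        _paint(img, _smooth_ball(d, s.refstruct_radius, self.edge), HU_REFSTRUCT)

        marker_c = (
            np.asarray(s.heart_center)
            + np.asarray(s.marker_offset0)
            + body_shift
            + heart_shift
            + np.asarray(motion.marker_offset)
        )
        d = self._sphere_dist(marker_c, rot, pivot + body_shift)
        _paint(img, _smooth_ball(d, s.marker_radius, self.edge), HU_MARKER)

        if s.streak_artifacts:
            self._paint_streaks(img, marker_c, rot, pivot + body_shift)

        if rng is not None and s.noise_sd_hu > 0:
            img += rng.normal(0.0, s.noise_sd_hu, size=img.shape)
        return img.astype(np.float32)


def _structure_positions(spec: PhantomSpec, motion: PhaseMotion):
    """Net mm displacement of marker and reference structure vs the primary."""
    body = np.asarray(motion.body_shift)
    heart = np.asarray(motion.heart_shift)
    pivot = np.asarray(spec.body_center) + body

    def net(p0: np.ndarray, extra: np.ndarray) -> np.ndarray:
        p = p0 + heart + extra  # pre-rotation position in body frame
        if any(motion.body_rot_deg):
            Rm = Rotation.from_euler(
                "ZYX", motion.body_rot_deg[::-1], degrees=True
            ).as_matrix()
            moved = Rm @ (p + body - pivot) + pivot
        else:
            moved = p + body
        return moved - p0

    m = net(spec.marker_center0(), np.asarray(motion.marker_offset))
    r = net(spec.refstruct_center0(), np.asarray(motion.refstruct_offset))
    return m, r


def _box_mask(grid: Grid, center: np.ndarray, half_mm: np.ndarray) -> np.ndarray:
    lo_idx = np.ceil(grid.physical_to_index(center - half_mm)).astype(int)
    hi_idx = np.floor(grid.physical_to_index(center + half_mm)).astype(int)
    lo_idx = np.clip(lo_idx, 0, np.asarray(grid.shape) - 1)
    hi_idx = np.clip(hi_idx, 0, np.asarray(grid.shape) - 1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1, lo_idx[2]:hi_idx[2] + 1] = True
    return mask


def _validate_inside(spec: PhantomSpec) -> None:
    lo, hi = spec.grid.extent_mm()
    pad = 6.0
    for motion in [PhaseMotion(phase="ebh")] + list(spec.motions):
        m, r = _structure_positions(spec, motion)
        for p0, net, rad in (
            (spec.marker_center0(), m, spec.marker_radius),
            (spec.refstruct_center0(), r, spec.refstruct_radius),
        ):
            p = p0 + net
            if np.any(p - rad < lo + pad) or np.any(p + rad > hi - pad):
                raise ValueError(
                    f"phase {motion.phase!r}: structure at {p.tolist()} mm leaves "
                    f"the usable grid [{(lo + pad).tolist()}, {(hi - pad).tolist()}]"
                )


def generate_series(spec: PhantomSpec) -> tuple[StudySet, GroundTruth]:
    """Render the full phantom study and its ground truth.

    Reproducible: the same spec (including seed) yields identical voxel
    data.  Raises before rendering if any programmed motion would push the
    marker or reference structure out of the usable grid.
    """
    _validate_inside(spec)
    grid = spec.grid
    renderer = _Renderer(spec)

    rng = np.random.default_rng(spec.seed)
    primary = ImageVolume(renderer.render(None, rng), grid, series_id="ebh")

    secondaries: list[ImageVolume] = []
    body_tf: dict[str, RigidTransform] = {}
    marker_net: dict[str, np.ndarray] = {}
    ref_net: dict[str, np.ndarray] = {}
    deformations: dict[str, DeformationVector] = {}
    for motion in spec.motions:
        vol = ImageVolume(renderer.render(motion, rng), grid, series_id=motion.phase)
        secondaries.append(vol)
        # renderer geometry is p_m = R (p_f - body_center) + body_center + b
        body_tf[motion.phase] = RigidTransform(
            translation=tuple(motion.body_shift),
            rotation_deg=tuple(motion.body_rot_deg[::-1]),
            center=tuple(spec.body_center),
            fixed_frame="ebh",
            moving_frame=motion.phase,
        )
        m, r = _structure_positions(spec, motion)
        marker_net[motion.phase] = m
        ref_net[motion.phase] = r
        deformations[motion.phase] = DeformationVector(motion.phase, tuple(r - m))

    # masks on the primary grid
    d_ctv = renderer._sphere_dist(spec.ctv_center0(), None, np.zeros(3))
    ctv = BinaryStructure(d_ctv <= spec.ctv_radius, grid, label="CTV")

    spine_c = np.array(
        [spec.spine_center_xy[0], spec.spine_center_xy[1], spec.body_center[2]]
    )
    spine_roi = BinaryStructure(
        _box_mask(grid, spine_c, np.array([spec.spine_radius + 8.0,
                                           spec.spine_radius + 8.0, 55.0])),
        grid,
        label="spine_roi",
    )
    motion_allowance = 15.0
    marker_roi = BinaryStructure(
        _box_mask(
            grid,
            spec.marker_center0(),
            np.full(3, spec.marker_radius + motion_allowance),
        ),
        grid,
        label="marker_roi",
    )
    ref_roi = BinaryStructure(
        _box_mask(grid, spec.refstruct_center0(), np.full(3, spec.refstruct_radius + 5.0)),
        grid,
        label="ref_roi",
    )

    study = StudySet(
        primary=primary,
        secondaries=secondaries,
        ctv=ctv,
        spine_roi=spine_roi,
        marker_roi=marker_roi,
        ref_roi=ref_roi,
    )
    truth = GroundTruth(
        body_transforms=body_tf,
        marker_net_mm=marker_net,
        refstruct_net_mm=ref_net,
        deformations=deformations,
    )
    return study, truth
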