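"""The triple registration chain on the synthetic phantom."""

import numpy as np
import pytest

from gdmtarget.core import BinaryStructure, ImageVolume, RigidTransform
from gdmtarget.phantom import PhantomSpec, PhaseMotion, generate_series
from gdmtarget.registration import (
    RegistrationResult,
    deformation_vector,
    detect_marker,
    register_spine_6d,
    register_translation_local,
    register_translation_marker,
    run_chain,
)


class TestDetectMarker:
    def test_single_bright_voxel_centroid(self, unit_grid):
        data = np.zeros(unit_grid.shape, np.float32)
        data[10, 20, 12] = 3000.0
        vol = ImageVolume(data, unit_grid)
        roi = BinaryStructure(np.ones(unit_grid.shape, bool), unit_grid, "roi")
        assert np.allclose(detect_marker(vol, roi), [10.0, 20.0, 12.0])

    def test_largest_component_wins(self, unit_grid):
        data = np.zeros(unit_grid.shape, np.float32)
        data[2:5, 2:5, 2:5] = 3000.0  # 27 voxels
        data[20, 20, 20] = 3000.0  # 1 voxel
        vol = ImageVolume(data, unit_grid)
        roi = BinaryStructure(np.ones(unit_grid.shape, bool), unit_grid)
        assert np.allclose(detect_marker(vol, roi), [3.0, 3.0, 3.0])

    def test_no_bright_voxel_errors(self, unit_grid):
        vol = ImageVolume(np.zeros(unit_grid.shape, np.float32), unit_grid)
        roi = BinaryStructure(np.ones(unit_grid.shape, bool), unit_grid)
        with pytest.raises(ValueError, match="marker not found"):
            detect_marker(vol, roi)

    def test_phantom_marker_within_half_voxel(self, phantom):
        spec, study, _ = phantom
        pos = detect_marker(study.primary, study.marker_roi)
        assert np.all(np.abs(pos - spec.marker_center0()) <= 0.5 * max(spec.spacing))

    def test_robust_to_streak_artifacts(self):
        spec = PhantomSpec(seed=8, streak_artifacts=True,
                           motions=[PhaseMotion(phase="ibh")])
        study, _ = generate_series(spec)
        assert np.count_nonzero(
            (study.primary.data > 1500) & study.marker_roi.mask
        ) > 25  # the spokes really do cross the detection threshold
        pos = detect_marker(study.primary, study.marker_roi)
        assert np.all(np.abs(pos - spec.marker_center0()) <= 0.5 * max(spec.spacing))


class TestSelfRegistration:
    """Registering the primary to itself recovers identity at every step."""

    def test_spine_identity(self, phantom):
        _, study, _ = phantom
        res = register_spine_6d(study.primary, study.primary, study.spine_roi)
        assert np.all(np.abs(res.transform.translation) < 0.1)
        assert np.all(np.abs(res.transform.rotation_deg) < 0.1)

    def test_marker_zero_increment(self, phantom):
        _, study, _ = phantom
        prior = RigidTransform.identity("ebh", "ebh")
        res = register_translation_marker(study.primary, study.primary,
                                          study.marker_roi, prior)
        assert np.all(np.abs(res.transform.translation) < 1e-6)

    def test_local_within_quarter_mm(self, phantom):
        _, study, _ = phantom
        prior = RigidTransform.identity("ebh", "ebh")
        res = register_translation_local(study.primary, study.primary,
                                         study.ref_roi, prior)
        assert np.all(np.abs(res.transform.translation) <= 0.25)


class TestChainOnPhantom:
    def test_deformation_recovery_within_one_voxel(self, phantom, phantom_chains):
        spec, _, truth = phantom
        voxel = max(spec.spacing)
        for chain in phantom_chains:
            err = chain.deformation.as_array() - truth.deformations[
                chain.series_id
            ].as_array()
            assert np.all(np.abs(err) <= voxel), (chain.series_id, err)

    def test_spine_recovers_body_shift_within_one_voxel(self, phantom, phantom_chains):
        spec, _, truth = phantom
        voxel = max(spec.spacing)
        for chain in phantom_chains:
            true_t = np.asarray(truth.body_transforms[chain.series_id].translation)
            est_t = np.asarray(chain.spine.transform.translation)
            assert np.all(np.abs(est_t - true_t) <= voxel)

    def test_marker_recovers_net_translation(self, phantom, phantom_chains):
        spec, _, truth = phantom
        voxel = max(spec.spacing)
        for chain in phantom_chains:
            est = np.asarray(chain.marker.transform.translation)
            true = truth.marker_net_mm[chain.series_id]
            assert np.all(np.abs(est - true) <= 0.5 * voxel)

    def test_rotation_frozen_after_spine(self, phantom_chains):
        for chain in phantom_chains:
            assert chain.marker.transform.rotation_deg == chain.spine.transform.rotation_deg
            assert chain.ref.transform.rotation_deg == chain.spine.transform.rotation_deg


class TestRotationRecovery:
    def test_two_degree_rotation_within_half_degree(self):
        spec = PhantomSpec(
            seed=2,
            motions=[PhaseMotion(phase="rot", body_rot_deg=(0.0, 0.0, 2.0),
                                 body_shift=(1.0, -2.0, 3.0))],
        )
        study, truth = generate_series(spec)
        res = register_spine_6d(study.primary, study.secondaries[0], study.spine_roi)
        assert abs(res.transform.rotation_deg[0] - 2.0) <= 0.5  # rz
        # transforms agree as maps even though rotation centres differ
        probe = np.array(spec.heart_center)
        true_map = truth.body_transforms["rot"].apply(probe)
        est_map = res.transform.apply(probe)
        assert np.all(np.abs(true_map - est_map) <= 0.5)


class TestEquivariance:
    def test_grid_aligned_shift_moves_recovered_translation(self, phantom):
        spec, study, _ = phantom
        sec = study.secondaries[1]
        v_vox = np.array([2, -1, 3])
        v_mm = v_vox * np.asarray(spec.spacing)
        rolled = ImageVolume(
            np.roll(sec.data, v_vox, axis=(0, 1, 2)), sec.grid, sec.series_id
        )
        base = register_spine_6d(study.primary, sec, study.spine_roi)
        moved = register_spine_6d(study.primary, rolled, study.spine_roi)
        delta = np.asarray(moved.transform.translation) - np.asarray(
            base.transform.translation
        )
        assert np.all(np.abs(delta - v_mm) <= 0.3)


class TestLocalRegistration:
    def test_flat_roi_errors(self, phantom):
        _, study, _ = phantom
        flat = ImageVolume(
            np.zeros(study.primary.grid.shape, np.float32), study.primary.grid, "flat"
        )
        with pytest.raises(ValueError, match="not discriminable"):
            register_translation_local(
                flat, flat, study.ref_roi, RigidTransform.identity()
            )

    def test_prior_rotation_copied_exactly(self, phantom):
        _, study, _ = phantom
        prior = RigidTransform(
            translation=(0.0, 0.0, 0.0),
            rotation_deg=(1.5, 0.0, 0.0),
            center=tuple(study.ref_roi.centroid_mm()),
        )
        res = register_translation_local(
            study.primary, study.primary, study.ref_roi, prior
        )
        assert res.transform.rotation_deg == prior.rotation_deg


class TestDeformationVector:
    def _result(self, t, series="fb1"):
        tf = RigidTransform(translation=t, fixed_frame="ebh", moving_frame=series)
        return RegistrationResult(tf, 0.0, "roi", 1)

    def test_identical_translations_zero(self):
        d = deformation_vector(self._result((1, 2, 3)), self._result((1, 2, 3)))
        assert d.d == (0.0, 0.0, 0.0)

    def test_componentwise_difference(self):
        d = deformation_vector(self._result((1, 2, 3)), self._result((3, 1, 3)))
        assert d.d == (2.0, -1.0, 0.0)

    def test_antisymmetric(self):
        a, b = self._result((1, 2, 3)), self._result((4, -1, 0))
        assert np.allclose(
            deformation_vector(a, b).as_array(), -deformation_vector(b, a).as_array()
        )

    def test_mismatched_series_errors(self):
        with pytest.raises(ValueError, match="different secondary series"):
            deformation_vector(
                self._result((0, 0, 0), "fb1"), self._result((0, 0, 0), "fb2")
            )
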