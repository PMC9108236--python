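"""GDM margin construction and target-volume expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmtarget.core import (
    AnatomicalMargin,
    BinaryStructure,
    DeformationVector,
    Grid,
    volume_cm3,
)
from gdmtarget.margins import (
    build_target_set,
    expand_anisotropic,
    expand_isotropic,
    gdm_margin,
    itv_gdm_sum,
)

from _oracles import brute_box_minkowski, brute_distance_expand, random_blob


def _vec(d, sid="s"):
    return DeformationVector(sid, tuple(d))


class TestGdmMargin:
    def test_componentwise_positive_part_max(self):
        m = gdm_margin([_vec((2.0, -1.0, 0.5), "a"), _vec((1.0, 1.5, -0.5), "b")])
        assert m.as_dict() == {
            "A": 1.0, "P": 1.5, "R": 0.0, "L": 2.0, "S": 0.5, "I": 0.5,
        }

    def test_zero_vector_gives_zero_margin(self):
        assert gdm_margin([_vec((0, 0, 0))]).is_zero

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            gdm_margin([])

    def test_matches_half_axis_brute_force(self):
        rng = np.random.default_rng(42)
        vs = [_vec(d, f"s{i}") for i, d in enumerate(rng.uniform(-5, 5, (100, 3)))]
        m = gdm_margin(vs)
        arr = np.array([v.d for v in vs])
        # brute force over the six signed half-axes
        assert m.left == pytest.approx(max(0.0, arr[:, 0].max()))
        assert m.right == pytest.approx(max(0.0, (-arr[:, 0]).max()))
        assert m.posterior == pytest.approx(max(0.0, arr[:, 1].max()))
        assert m.anterior == pytest.approx(max(0.0, (-arr[:, 1]).max()))
        assert m.superior == pytest.approx(max(0.0, arr[:, 2].max()))
        assert m.inferior == pytest.approx(max(0.0, (-arr[:, 2]).max()))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(*[st.floats(-10, 10, allow_nan=False) for _ in range(3)]),
            min_size=1, max_size=10,
        )
    )
    def test_margin_dominates_every_vector(self, ds):
        m = gdm_margin([_vec(d, f"s{i}") for i, d in enumerate(ds)])
        lo, hi = m.low_high_mm()
        for d in ds:
            assert np.all(np.asarray(d) <= hi + 1e-12)
            assert np.all(np.asarray(d) >= -lo - 1e-12)


class TestAnisotropicExpansion:
    def test_zero_margin_identity(self, cube):
        out = expand_anisotropic(cube, AnatomicalMargin())
        assert np.array_equal(out.mask, cube.mask)

    def test_left_only_box_growth(self, cube):
        # 10 mm cube at 1 mm spacing, 2 mm left margin: 1.00 -> 1.20 cm^3
        out = expand_anisotropic(cube, AnatomicalMargin(left=2.0))
        assert volume_cm3(cube) == pytest.approx(1.0)
        assert volume_cm3(out) == pytest.approx(1.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_minkowski(self, seed):
        shape = (32, 32, 32)
        grid = Grid(shape, (1.0, 1.5, 2.0))
        rng = np.random.default_rng(seed)
        ctv = BinaryStructure(random_blob((20, 20, 20), rng, n_seeds=2), Grid((20, 20, 20), (1, 1.5, 2)))
        padded = np.zeros(shape, bool)
        padded[6:26, 6:26, 6:26] = ctv.mask
        s = BinaryStructure(padded, grid, "CTV")
        margin = AnatomicalMargin(*(rng.uniform(0, 4, size=6)))
        out = expand_anisotropic(s, margin)
        lo, hi = margin.low_high_mm()
        spacing = np.asarray(grid.spacing)
        low_vox = np.ceil(lo / spacing - 1e-6).astype(int)
        high_vox = np.ceil(hi / spacing - 1e-6).astype(int)
        expected = brute_box_minkowski(s.mask, low_vox, high_vox)
        assert np.array_equal(out.mask, expected)

    def test_expansion_beyond_grid_errors(self, cube):
        with pytest.raises(ValueError, match="pad the grid"):
            expand_anisotropic(cube, AnatomicalMargin(left=20.0))

    def test_ellipsoid_kernel_is_subset_of_box(self, cube):
        m = AnatomicalMargin(left=4.0, posterior=3.0, superior=5.0, inferior=2.0)
        box = expand_anisotropic(cube, m, kernel="box")
        ell = expand_anisotropic(cube, m, kernel="ellipsoid")
        assert not np.any(ell.mask & ~box.mask)
        assert not np.any(cube.mask & ~ell.mask)  # still contains the CTV


class TestIsotropicExpansion:
    def test_zero_radius_identity(self, cube):
        assert np.array_equal(expand_isotropic(cube, 0.0).mask, cube.mask)

    def test_single_voxel_digital_ball(self):
        grid = Grid((11, 11, 11), (1.0, 1.0, 1.0))
        m = np.zeros(grid.shape, bool)
        m[5, 5, 5] = True
        out = expand_isotropic(BinaryStructure(m, grid), 2.0)
        assert out.voxel_count == 33

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_distance_oracle(self, seed):
        shape = (30, 30, 30)
        grid = Grid(shape, (1.0, 1.0, 1.5))
        rng = np.random.default_rng(seed)
        inner = random_blob((16, 16, 16), rng, n_seeds=2)
        padded = np.zeros(shape, bool)
        padded[7:23, 7:23, 7:23] = inner
        s = BinaryStructure(padded, grid)
        r = float(rng.uniform(1.0, 4.0))
        out = expand_isotropic(s, r)
        assert np.array_equal(out.mask, brute_distance_expand(s.mask, r, grid.spacing))


class TestGdmSum:
    def test_no_vectors_is_ctv(self, cube):
        out = itv_gdm_sum(cube, [])
        assert np.array_equal(out.mask, cube.mask)

    def test_one_voxel_pitch_union(self, cube):
        out = itv_gdm_sum(cube, [_vec((0, 0, 1.0))])
        expected = cube.mask | np.roll(cube.mask, 1, axis=2)
        assert np.array_equal(out.mask, expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_volume_matches_inclusion_exclusion_count(self, seed):
        grid = Grid((40, 40, 40), (1.0, 1.0, 1.0))
        rng = np.random.default_rng(seed)
        inner = random_blob((20, 20, 20), rng, n_seeds=2)
        padded = np.zeros(grid.shape, bool)
        padded[10:30, 10:30, 10:30] = inner
        ctv = BinaryStructure(padded, grid, "CTV")
        ds = rng.uniform(-4, 4, (3, 3))
        out = itv_gdm_sum(ctv, [_vec(d, f"s{i}") for i, d in enumerate(ds)])
        # independent voxel-set union oracle
        pts = set(map(tuple, np.argwhere(ctv.mask)))
        union = set(pts)
        for d in ds:
            shift = tuple(int(np.copysign(np.floor(abs(x) + 0.5), x)) for x in d)
            union |= {(i + shift[0], j + shift[1], k + shift[2]) for i, j, k in pts}
        assert out.voxel_count == len(union)

    def test_shift_out_of_grid_errors(self, cube):
        with pytest.raises(ValueError, match="outside the grid"):
            itv_gdm_sum(cube, [_vec((8.0, 0, 0))])


class TestTargetSet:
    def test_zero_everything_collapses_to_ctv(self, cube):
        ts = build_target_set(cube, [], iso_margin_mm=0.0)
        for s in (ts.itv_gdm, ts.itv_gdm_sum, ts.ptv_gdm, ts.ptv_gdm_sum):
            assert np.array_equal(s.mask, cube.mask)
        assert ts.margin.is_zero

    def test_containment_chain_and_sum_smaller(self, cube):
        rng = np.random.default_rng(5)
        vs = [_vec(d, f"s{i}") for i, d in enumerate(rng.uniform(-3, 3, (4, 3)))]
        ts = build_target_set(cube, vs, iso_margin_mm=2.0)
        assert ts.containment_ok()
        assert volume_cm3(ts.itv_gdm_sum) <= volume_cm3(ts.itv_gdm)
        # non-empty masks grow strictly under a positive isotropic margin
        assert ts.ptv_gdm.voxel_count > ts.itv_gdm.voxel_count
        assert ts.ptv_gdm_sum.voxel_count > ts.itv_gdm_sum.voxel_count

    def test_volume_monotone_in_margin(self, cube):
        base = AnatomicalMargin(left=1.0, posterior=2.0)
        bigger = AnatomicalMargin(left=3.0, posterior=2.0, inferior=1.0)
        v_base = volume_cm3(expand_anisotropic(cube, base))
        v_big = volume_cm3(expand_anisotropic(cube, bigger))
        assert v_big >= v_base

    def test_sum_dice_below_one_when_margin_exceeds_footprint(self, cube):
        from gdmtarget.metrics import dice

        # two opposing vectors make the box strictly larger than the union
        vs = [_vec((3.0, 0, 0), "a"), _vec((-3.0, 0, 0), "b"), _vec((0, 3.0, 0), "c")]
        ts = build_target_set(cube, vs, iso_margin_mm=0.0)
        assert dice(ts.itv_gdm, ts.itv_gdm_sum) < 1.0
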