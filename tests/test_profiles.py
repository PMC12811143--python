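import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomorph import profiles as prof
from cardiomorph.exceptions import AlignmentError, DegenerateProfileError
from cardiomorph.profiles import (
    BoundaryStat,
    LinearProfile,
    ProfileLine,
    aggregate_profiles,
    boundary_stats,
    chamber_area_fractions,
    compare_boundaries,
    compare_chamber_fractions,
    normalize_profile,
    pointwise_welch,
    sample_profile,
    slab_max_projection,
    subtract_background,
)
from cardiomorph.synthetic import BoundaryPhantomSpec, make_boundary_volume
from cardiomorph.volume import MultiChannelVolume


class TestSubtractBackground:
    def test_constant_image_removed(self):
        out = subtract_background(np.full((80, 80), 37.0), radius_px=10)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_peak_preserved(self):
        img = np.full((128, 128), 10.0)
        img[60:63, 60:63] += 100.0
        out = subtract_background(img, radius_px=50)
        assert out[61, 61] == pytest.approx(100.0, rel=0.05)

    def test_smooth_gradient_removed(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        img = 50.0 * xx / 127.0  # length scale >> radius
        out = subtract_background(img, radius_px=20)
        assert out.max() < 0.1 * 50.0

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((4, 4, 4)))


class TestSlabProjection:
    def _volume(self, data):
        return MultiChannelVolume(
            data=data[None], voxel_size_um=(10.0, 2.0, 2.0), channel_names=("c",)
        )

    def test_count(self):
        vol = self._volume(np.zeros((20, 8, 8)))  # 200 um stack
        assert len(slab_max_projection(vol, 50.0, "c")) == 4

    def test_constant(self):
        vol = self._volume(np.full((20, 8, 8), 3.0))
        for proj in slab_max_projection(vol, 50.0, "c"):
            np.testing.assert_array_equal(proj, 3.0)

    def test_single_voxel_in_one_slab(self):
        data = np.zeros((20, 8, 8))
        data[7, 4, 4] = 9.0
        vol = self._volume(data)
        hits = [proj.max() == 9.0 for proj in slab_max_projection(vol, 50.0, "c")]
        assert sum(hits) == 1

    def test_oversized_slab_warns(self):
        vol = self._volume(np.zeros((4, 8, 8)))
        with pytest.warns(UserWarning):
            projs = slab_max_projection(vol, 1000.0, "c")
        assert len(projs) == 1


class TestSampleProfile:
    def test_on_grid(self):
        img = np.zeros((5, 3))
        img[1] = [3.0, 7.0, 9.0]
        line = ProfileLine(start=(1.0, 0.0), end=(1.0, 2.0), sampling_step_um=1.0)
        p = sample_profile(img, line, pixel_size_um=1.0)
        np.testing.assert_allclose(p.intensities, [3.0, 7.0, 9.0])

    def test_anchor_at_midpoint(self):
        img = np.zeros((3, 101))
        line = ProfileLine(
            start=(1.0, 0.0), end=(1.0, 100.0), anchor_um=50.0, sampling_step_um=1.0
        )
        p = sample_profile(img, line, pixel_size_um=1.0)
        assert p.positions_um[0] == -50.0
        assert p.positions_um[-1] == 50.0

    def test_diagonal_ramp_bilinear(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        img = 2.0 * xx + 3.0 * yy  # bilinear interp of a ramp is exact
        line = ProfileLine(start=(0.0, 0.0), end=(20.0, 20.0), sampling_step_um=5.0)
        p = sample_profile(img, line, pixel_size_um=1.0)
        length = np.hypot(20, 20)
        frac = p.positions_um / length
        expected = 2.0 * (frac * 20.0) + 3.0 * (frac * 20.0)
        np.testing.assert_allclose(p.intensities, expected, atol=1e-9)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            sample_profile(
                np.zeros((4, 4)),
                ProfileLine(start=(0.0, 0.0), end=(10.0, 0.0)),
            )


class TestNormalize:
    def test_arithmetic(self):
        p = LinearProfile([0.0, 1.0, 2.0], [2.0, 4.0, 8.0])
        out = normalize_profile(p)
        np.testing.assert_allclose(out.intensities, [0.25, 0.5, 1.0])
        assert out.normalized

    def test_idempotent(self):
        p = normalize_profile(LinearProfile([0.0, 1.0], [1.0, 3.0]))
        again = normalize_profile(p)
        np.testing.assert_array_equal(p.intensities, again.intensities)

    def test_zero_profile_rejected(self):
        with pytest.raises(DegenerateProfileError):
            normalize_profile(LinearProfile([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]))


class TestAggregate:
    def test_identical_profiles_zero_sem(self):
        p = normalize_profile(LinearProfile(np.arange(5.0), [1, 2, 3, 4, 5.0]))
        ens = aggregate_profiles([p, p])
        np.testing.assert_allclose(ens.sem, 0.0)

    def test_identity_mean(self):
        p = normalize_profile(LinearProfile([0.0, 1.0], [0.5, 1.0]))
        ens = aggregate_profiles([p, p], grid_step_um=1.0)
        np.testing.assert_allclose(ens.mean, [0.5, 1.0])

    def test_shifted_grids_match_hand_resampling(self):
        a = normalize_profile(
            LinearProfile([-2.5, -0.5, 1.5, 3.5], [0.2, 0.4, 0.8, 1.0])
        )
        b = normalize_profile(LinearProfile([-2.0, 0.0, 2.0, 4.0], [0.1, 0.5, 1.0, 0.9]))
        ens = aggregate_profiles([a, b], grid_step_um=1.0)
        # hand-interpolated values at positions -2, 0, 1
        for pos, va, vb in [
            (-2.0, 0.2 + 0.5 / 2.0 * 0.2, 0.1),
            (0.0, 0.4 + 0.5 / 2.0 * 0.4, 0.5),
            (1.0, 0.4 + 1.5 / 2.0 * 0.4, 0.75),
        ]:
            i = int(np.flatnonzero(ens.positions_um == pos)[0])
            assert ens.matrix[0, i] == pytest.approx(va)
            assert ens.matrix[1, i] == pytest.approx(vb)
        np.testing.assert_allclose(ens.mean, ens.matrix.mean(axis=0))

    def test_order_independence(self):
        profiles = [
            normalize_profile(LinearProfile(np.arange(4.0), np.arange(1.0, 5.0) * k))
            for k in (1.0, 2.0, 3.0)
        ]
        e1 = aggregate_profiles(profiles)
        e2 = aggregate_profiles(profiles[::-1])
        np.testing.assert_allclose(e1.mean, e2.mean)
        np.testing.assert_allclose(e1.sem, e2.sem)

    def test_empty_overlap(self):
        a = normalize_profile(LinearProfile([0.0, 1.0], [1.0, 1.0]))
        b = normalize_profile(LinearProfile([10.0, 11.0], [1.0, 1.0]))
        with pytest.raises(AlignmentError):
            aggregate_profiles([a, b])


class TestPointwiseWelch:
    def _ensemble(self, matrix):
        return prof.ProfileEnsemble(
            positions_um=np.arange(matrix.shape[1], dtype=float), matrix=matrix
        )

    def test_identical_groups_nothing_significant(self, rng):
        m = rng.random((5, 10))
        res = pointwise_welch(self._ensemble(m), self._ensemble(m.copy()))
        assert not res.significant.any()
        assert res.runs_um == []

    def test_shifted_logistic_centers_detected(self, rng):
        from scipy.special import expit

        x = np.arange(-60.0, 61.0)
        a = expit(x / 10.0)[None, :] + rng.normal(0, 0.05, (20, x.size))
        b = expit((x - 40.0) / 10.0)[None, :] + rng.normal(0, 0.05, (20, x.size))
        ea = prof.ProfileEnsemble(positions_um=x, matrix=a)
        eb = prof.ProfileEnsemble(positions_um=x, matrix=b)
        res = pointwise_welch(ea, eb)
        between = (res.positions_um > 5) & (res.positions_um < 35)
        assert res.significant[between].all()

    def test_small_group_gives_nan(self, rng):
        a = self._ensemble(rng.random((1, 4)))
        b = self._ensemble(rng.random((5, 4)))
        res = pointwise_welch(a, b)
        assert np.isnan(res.p_values).all()


class TestBoundaryStats:
    def test_point_mass(self):
        p = LinearProfile([-20.0, -10.0, 0.0, 10.0, 20.0], [0, 0, 1, 0, 0.0])
        st_ = boundary_stats(p)
        assert st_.m == 0.0 and st_.s == 0.0

    def test_uniform_second_moment(self):
        p = LinearProfile([-20.0, -10.0, 0.0, 10.0, 20.0], np.ones(5))
        st_ = boundary_stats(p)
        assert st_.m == pytest.approx(0.0)
        assert st_.s == pytest.approx(np.sqrt(200.0))

    def test_symmetric_bimodal(self):
        p = LinearProfile([-30.0, -20.0, 0.0, 20.0, 30.0], [1, 5, 0, 5, 1.0])
        assert boundary_stats(p).m == pytest.approx(0.0)

    def test_zero_intensity_rejected(self):
        with pytest.raises(DegenerateProfileError):
            boundary_stats(LinearProfile([0.0, 1.0], [0.0, 0.0]))

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_equivariance(self, shift, scale):
        x = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        w = np.array([0.1, 0.5, 1.0, 0.7, 0.2])
        base = boundary_stats(LinearProfile(x, w))
        shifted = boundary_stats(LinearProfile(x + shift, w))
        scaled = boundary_stats(LinearProfile(x, w * scale))
        assert shifted.m == pytest.approx(base.m + shift, abs=1e-6)
        assert shifted.s == pytest.approx(base.s, abs=1e-6)
        assert scaled.m == pytest.approx(base.m, abs=1e-9)
        assert scaled.s == pytest.approx(base.s, abs=1e-9)


class TestCompareBoundaries:
    def _stats(self, ms):
        return [BoundaryStat(m=float(m), s=1.0, total_intensity=1.0) for m in ms]

    def test_identical_groups(self):
        a = self._stats([1.0, 2.0, 3.0])
        res = compare_boundaries(a, self._stats([1.0, 2.0, 3.0]))
        assert res.t_statistic == 0.0
        assert res.p_means == 1.0
        assert res.f_statistic == pytest.approx(1.0)

    def test_constant_shift_detected(self, rng):
        ms = rng.normal(0.0, 5.0, 20)
        res = compare_boundaries(self._stats(ms), self._stats(ms + 30.0))
        assert res.p_means < 0.01

    def test_spread_inflation_detected(self, rng):
        a = rng.normal(0.0, 5.0, 50)
        b = rng.normal(0.0, 20.0, 50)
        res = compare_boundaries(self._stats(a), self._stats(b))
        # true ratio 1/16; allow generous sampling scatter at n = 50
        assert 0.02 < res.f_statistic < 0.2
        assert res.p_variances < 1e-6

    def test_degenerate_zero_variance(self):
        res = compare_boundaries(self._stats([2.0, 2.0]), self._stats([2.0, 2.0]))
        assert res.degenerate
        assert res.p_means == 1.0


class TestChamberFractions:
    def test_containment(self):
        img = np.zeros((20, 20))
        img[5:10, 2:8] = 10.0
        roi_lv = np.zeros((20, 20), bool)
        roi_lv[:, :10] = True
        roi_rv = ~roi_lv
        res = chamber_area_fractions(img, roi_lv, roi_rv, threshold_method=1.0)
        assert res.lv_pct[0] == 100.0
        assert res.rv_pct[0] == 0.0

    def test_even_split(self):
        img = np.zeros((20, 20))
        img[5:10, 2:8] = 10.0
        img[5:10, 12:18] = 10.0
        roi_lv = np.zeros((20, 20), bool)
        roi_lv[:, :10] = True
        res = chamber_area_fractions(img, roi_lv, ~roi_lv, threshold_method=1.0)
        assert res.lv_pct[0] == pytest.approx(50.0)

    def test_known_split_phantom(self, rng):
        # 70/30 split by construction: 196 signal px in LV, 84 in RV
        img = rng.normal(0.0, 0.01, (64, 64))
        img[10:17, 2:30] = 1.0  # 7 x 28 = 196 px, cols < 32
        img[40:47, 40:52] = 1.0  # 7 x 12 = 84 px, cols >= 32
        roi_lv = np.zeros((64, 64), bool)
        roi_lv[:, :32] = True
        res = chamber_area_fractions(img, roi_lv, ~roi_lv, threshold_method=0.5)
        assert res.lv_pct[0] == pytest.approx(70.0, abs=2.0)
        assert res.rv_pct[0] == pytest.approx(30.0, abs=2.0)

    def test_empty_slice_excluded(self):
        imgs = np.zeros((2, 10, 10))
        imgs[1, 2, 2] = 5.0
        roi_lv = np.zeros((10, 10), bool)
        roi_lv[:, :5] = True
        res = chamber_area_fractions(imgs, roi_lv, ~roi_lv, threshold_method=1.0)
        assert list(res.slices_excluded) == [0]
        assert list(res.slices_used) == [1]


class TestCompareChamberFractions:
    def test_identical(self):
        t, p = compare_chamber_fractions([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert t == 0.0 and p == 1.0

    def test_separated_groups(self, rng):
        a = rng.normal(5.0, 5.0, 10)
        b = rng.normal(30.0, 5.0, 10)
        _, p = compare_chamber_fractions(a, b)
        assert p < 0.01

    def test_label_swap_symmetry(self, rng):
        a = rng.normal(5.0, 5.0, 10)
        b = rng.normal(12.0, 5.0, 10)
        _, p1 = compare_chamber_fractions(a, b)
        _, p2 = compare_chamber_fractions(b, a)
        assert p1 == pytest.approx(p2)


def test_noiseless_phantom_center_recovery_sweep():
    for center in (-150.0, -75.0, 0.0, 75.0, 150.0):
        spec = BoundaryPhantomSpec(
            shape_px=(4, 16, 256),
            voxel_size_um=(10.0, 2.0, 2.0),
            boundary_center_um=center,
        )
        vol, _ = make_boundary_volume(spec)
        proj = slab_max_projection(vol, 40.0, "band")[0]
        nx = proj.shape[1]
        line = ProfileLine(
            start=(8.0, 0.0), end=(8.0, nx - 1.0), anchor_um=(nx - 1) * 1.0,
            sampling_step_um=2.0,
        )
        p = normalize_profile(sample_profile(proj, line, pixel_size_um=2.0))
        assert boundary_stats(p).m == pytest.approx(center, abs=2.0)
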