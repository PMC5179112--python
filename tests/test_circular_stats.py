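"""Circular statistics: closed-form cases, equivariances, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respigate.circular_stats import (
    PolarProfile,
    bin_polar,
    bin_polar_trials,
    centroid,
    circular_median,
    compare_conditions,
    equal_medians_test,
    rayleigh_test,
    rotate_and_scale,
    rotate_profile,
    signed_angle_diff,
    wrap_angle,
)


def vm(rng, mu, kappa, n):
    return rng.vonmises(mu, kappa, n) % (2 * np.pi)


class TestBinPolar:
    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 100)
        prof = bin_polar(ang, n_bins=12)
        assert prof.rate.sum() == 100
        assert prof.n_obs.sum() == 100

    def test_single_bin_occupancy(self):
        prof = bin_polar(np.full(7, np.pi / 3), n_bins=12)
        hot = int(np.pi / 3 / (2 * np.pi) * 12)
        assert prof.rate[hot] == 7
        assert prof.rate.sum() == 7

    def test_uniform_grid_one_per_bin(self):
        ang = (np.arange(12) + 0.5) * 2 * np.pi / 12
        prof = bin_polar(ang, n_bins=12)
        np.testing.assert_array_equal(prof.rate, np.ones(12))

    def test_exposure_gives_rates_in_hz(self):
        prof = bin_polar([0.1] * 10, n_bins=2, exposure=5.0)
        assert prof.rate[0] == pytest.approx(2.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bin_polar([], n_bins=6)


class TestCentroid:
    def test_point_mass(self):
        c = centroid(np.full(20, np.pi / 3))
        assert c.angle == pytest.approx(np.pi / 3)
        assert c.magnitude == pytest.approx(1.0)

    def test_symmetric_pair_bisects(self):
        c = centroid(np.array([0.0, np.pi / 2]))
        assert c.angle == pytest.approx(np.pi / 4)

    def test_antipodal_flagged_undefined(self):
        c = centroid(np.array([0.0, np.pi]))
        assert not c.defined
        assert c.magnitude == 0.0

    def test_profile_summaries(self):
        edges = np.linspace(0, 2 * np.pi, 7)
        rate = np.array([4.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        prof = PolarProfile(edges, rate, np.zeros(6), np.ones(6))
        c = centroid(prof)
        assert c.peak_rate == 4.0
        assert c.mean_rate == pytest.approx(1.5)
        assert c.polar_area == pytest.approx(0.5 * np.sum(rate**2) * np.pi / 3)
        assert abs(signed_angle_diff(c.angle, edges[0] + np.pi / 6)) < 1e-9

    @given(st.integers(0, 1000), st.floats(-10, 10))
    @settings(max_examples=40, deadline=None)
    def test_rotation_equivariance(self, seed, delta):
        rng = np.random.default_rng(seed)
        ang = vm(rng, 1.0, 2.0, 30)
        base = centroid(ang)
        rot = centroid(wrap_angle(ang + delta))
        assert abs(signed_angle_diff(rot.angle, base.angle + delta)) < 1e-9
        assert rot.magnitude == pytest.approx(base.magnitude)

    def test_scale_invariance_and_area_quadratic(self):
        edges = np.linspace(0, 2 * np.pi, 13)
        rng = np.random.default_rng(5)
        rate = rng.uniform(1, 10, 12)
        prof = PolarProfile(edges, rate, np.zeros(12), np.ones(12))
        c1, c3 = centroid(prof), centroid(prof.scaled(3.0))
        assert c3.angle == pytest.approx(c1.angle)
        assert c3.peak_rate == pytest.approx(3 * c1.peak_rate)
        assert c3.mean_rate == pytest.approx(3 * c1.mean_rate)
        assert c3.polar_area == pytest.approx(9 * c1.polar_area)


class TestRayleigh:
    def test_maximal_concentration(self):
        r = rayleigh_test(np.zeros(50))
        assert r["z"] == pytest.approx(50.0)
        assert r["p"] < 1e-10

    def test_equally_spaced_is_uniform(self):
        r = rayleigh_test(np.arange(12) * 2 * np.pi / 12)
        assert r["z"] == pytest.approx(0.0, abs=1e-20)
        assert r["p"] > 0.99

    def test_type_one_error_calibrated(self):
        # rejection rate at alpha=0.05 over 2000 uniform samples of n=50
        rng = np.random.default_rng(42)
        rejections = sum(
            rayleigh_test(rng.uniform(0, 2 * np.pi, 50))["p"] < 0.05
            for _ in range(2000))
        assert 0.03 <= rejections / 2000 <= 0.07

    def test_small_n_guard(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0, 2.0])


class TestCircularMedian:
    def test_concentrated_sample(self):
        rng = np.random.default_rng(1)
        ang = vm(rng, np.pi / 3, 8.0, 101)
        med = circular_median(ang)
        assert abs(signed_angle_diff(med, np.pi / 3)) < 0.2

    def test_wraparound_sample(self):
        # mass straddling 0 must not report a median near pi
        ang = np.array([6.1, 6.2, 0.1, 0.2, 0.15])
        med = circular_median(ang)
        assert min(med, 2 * np.pi - med) < 0.5


class TestEqualMedians:
    def test_identical_concentrated_groups_not_rejected(self):
        rng = np.random.default_rng(2)
        g = vm(rng, 1.0, 4.0, 60)
        res = equal_medians_test([g, g.copy()])
        assert res["p"] > 0.2

    def test_antipodal_groups_rejected(self):
        rng = np.random.default_rng(3)
        res = equal_medians_test([vm(rng, 0.0, 4.0, 50),
                                  vm(rng, np.pi, 4.0, 50)])
        assert res["p"] < 0.01

    def test_null_calibration_three_groups(self):
        # three groups from one von Mises: rejection rate near alpha
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            groups = [vm(rng, 1.0, 2.0, 30) for _ in range(3)]
            rejections += equal_medians_test(groups)["p"] < 0.05
        assert 0.01 <= rejections / n_sim <= 0.10

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            equal_medians_test([[0.1, 0.2, 0.3, 0.4], [1.0] * 10])


class TestRotateAndScale:
    def _profile(self, rate):
        rate = np.asarray(rate, dtype=float)
        edges = np.linspace(0, 2 * np.pi, rate.size + 1)
        return PolarProfile(edges, rate, np.zeros(rate.size),
                            np.ones(rate.size))

    def test_control_centroid_moved_to_zero(self):
        rate = np.array([1, 2, 8, 2, 1, 1, 1, 1, 1, 1, 1, 1.0])  # peak near pi/2
        ctrl = self._profile(rate)
        out = rotate_and_scale([(ctrl, ctrl)])
        c = centroid(out["ctrl_mean"])
        assert min(c.angle, 2 * np.pi - c.angle) < 0.15
        assert out["ctrl_mean"].rate.max() == pytest.approx(1.0, abs=1e-9)

    def test_identical_pairs_have_zero_group_se(self):
        p = self._profile([1, 3, 6, 3, 1, 1, 1, 1, 1, 1, 1, 1.0])
        out = rotate_and_scale([(p, p)] * 5)
        np.testing.assert_allclose(out["stim_mean"].rate,
                                   out["ctrl_mean"].rate)
        np.testing.assert_allclose(out["stim_mean"].se, 0.0, atol=1e-12)

    def test_rotation_equivariance_of_alignment(self):
        ctrl = self._profile([1, 3, 9, 3, 1, 1, 1, 1, 1, 1, 1, 1.0])
        delta = 2 * np.pi / 12 * 3  # rotate stim three bins later
        stim = rotate_profile(ctrl, delta)
        out = rotate_and_scale([(stim, ctrl)])
        cs = centroid(out["stim_mean"])
        cc = centroid(out["ctrl_mean"])
        assert signed_angle_diff(cs.angle, cc.angle) == pytest.approx(
            delta, abs=0.05)

    def test_degenerate_controls_excluded(self):
        flat = self._profile(np.zeros(12))
        good = self._profile([1, 5, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1.0])
        out = rotate_and_scale([(good, good), (good, flat)])
        assert out["n_units"] == 1
        assert out["n_excluded"] == 1


class TestCompareConditions:
    def _profile(self, rate):
        rate = np.asarray(rate, dtype=float)
        edges = np.linspace(0, 2 * np.pi, rate.size + 1)
        return PolarProfile(edges, rate, np.zeros(rate.size),
                            np.ones(rate.size))

    def test_identity(self):
        p = self._profile([1, 4, 2, 1, 1, 1.0])
        res = compare_conditions(p, p)
        assert res["delta_centroid"] == pytest.approx(0.0)
        for key in ("mean_rate_ratio", "peak_rate_ratio", "polar_area_ratio"):
            assert res[key] == pytest.approx(1.0)

    def test_doubling(self):
        p = self._profile([1, 4, 2, 1, 1, 1.0])
        res = compare_conditions(p.scaled(2.0), p)
        assert res["delta_centroid"] == pytest.approx(0.0, abs=1e-9)
        assert res["mean_rate_ratio"] == pytest.approx(2.0)
        assert res["peak_rate_ratio"] == pytest.approx(2.0)
        assert res["polar_area_ratio"] == pytest.approx(4.0)

    def test_rotation_by_reference_shift(self):
        # a -0.75 rad rotation (the reference gating effect size) is
        # recovered as a negative (earlier-phase) centroid shift
        ctrl = self._profile([1, 2, 6, 9, 6, 2, 1, 1, 1, 1, 1, 1.0])
        stim = rotate_profile(ctrl, -0.75)
        res = compare_conditions(stim, ctrl)
        assert res["delta_centroid"] == pytest.approx(-0.75, abs=0.05)


def test_bin_polar_trials_mean_and_se():
    trials = [np.array([0.1, 0.1]), np.array([0.1]), np.array([0.1, 0.1])]
    prof = bin_polar_trials(trials, n_bins=4, trial_exposure=1.0)
    assert prof.rate[0] == pytest.approx(5 / 3)
    assert prof.rate[1:].sum() == 0
    expected_se = np.std([2, 1, 2], ddof=1) / np.sqrt(3)
    assert prof.se[0] == pytest.approx(expected_se)
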