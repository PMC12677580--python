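"""Axial circular statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chiralign import (
    AngleSample,
    ci_mean_axial,
    circular_mean_axial,
    circular_sd_axial,
    double_angles,
    frequency_distribution,
    generate_angle_sample,
    halve_angles,
    mean_resultant_axial,
    one_sample_mean_test,
    summarize,
    watson_u2_test,
    wrap_axial,
)
from chiralign.circstats import watson_u2_stat
from chiralign.errors import UndefinedMeanError

from conftest import vonmises_sd_half_deg


def brute_mean(angles_deg):
    """Independent oracle: mean of doubled unit vectors, halved."""
    a = np.deg2rad(2.0 * np.asarray(angles_deg, float))
    m = np.rad2deg(np.arctan2(np.sin(a).sum(), np.cos(a).sum())) / 2.0
    return float(wrap_axial(m))


class TestDoubling:
    def test_minus45_maps_to_270(self):
        assert double_angles(AngleSample("x", np.array([-45.0]))) == [270.0]

    def test_zero_and_ninety(self):
        out = double_angles(AngleSample("x", np.array([0.0, 90.0])))
        assert list(out) == [0.0, 180.0]

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(-90.0, 90.0, 1000)
        th[th == -90.0] = 90.0
        back = halve_angles(double_angles(AngleSample("x", th)))
        assert np.allclose(back, th, atol=1e-9)

    @given(st.floats(-1e4, 1e4, allow_nan=False))
    def test_wrap_axial_range_and_idempotence(self, x):
        w = wrap_axial(x)
        assert -90.0 < w <= 90.0
        assert wrap_axial(w) == w


class TestMeanAndSD:
    def test_constant_sample(self):
        s = AngleSample("x", np.full(3, 20.0))
        assert circular_mean_axial(s) == pytest.approx(20.0, abs=1e-9)

    def test_symmetric_triplet(self):
        s = AngleSample("x", np.array([10.0, 20.0, 30.0]))
        assert circular_mean_axial(s) == pytest.approx(brute_mean(s.angles_deg),
                                                       abs=1e-9)
        assert circular_mean_axial(s) == pytest.approx(20.0, abs=1e-6)

    def test_balanced_pair_is_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean_axial(AngleSample("x", np.array([-45.0, 45.0])))

    def test_sd_zero_for_degenerate(self):
        assert circular_sd_axial(AngleSample("x", np.full(4, 30.0))) == \
            pytest.approx(0.0, abs=1e-6)

    def test_sd_matches_vonmises_closed_form(self):
        s = generate_angle_sample(10_000, 0.0, 5.0, seed=42)
        expected = vonmises_sd_half_deg(5.0)
        assert circular_sd_axial(s) == pytest.approx(expected, rel=0.02)

    def test_mean_recovery_against_brute_force(self):
        s = generate_angle_sample(10_000, -7.5, 5.0, seed=7)
        assert circular_mean_axial(s) == pytest.approx(
            brute_mean(s.angles_deg), abs=1e-9)
        assert abs(circular_mean_axial(s) - (-7.5)) < 1.0

    def test_axial_invariance_under_180_shift(self):
        base = generate_angle_sample(500, -20.0, 4.0, seed=3)
        shifted = AngleSample.from_degrees("x", base.angles_deg + 180.0)
        assert circular_mean_axial(shifted) == pytest.approx(
            circular_mean_axial(base), abs=1e-9)
        assert circular_sd_axial(shifted) == pytest.approx(
            circular_sd_axial(base), abs=1e-9)

    def test_reflection_antisymmetry(self):
        a = generate_angle_sample(400, -15.0, 4.0, seed=9, label="a")
        b = generate_angle_sample(400, 25.0, 3.0, seed=10, label="b")
        na = AngleSample.from_degrees("na", -a.angles_deg)
        nb = AngleSample.from_degrees("nb", -b.angles_deg)
        assert circular_mean_axial(na) == pytest.approx(
            -circular_mean_axial(a), abs=1e-6)
        assert circular_sd_axial(na) == pytest.approx(
            circular_sd_axial(a), abs=1e-9)
        assert mean_resultant_axial(na) == pytest.approx(
            mean_resultant_axial(a), abs=1e-12)
        assert watson_u2_stat(na, nb) == pytest.approx(
            watson_u2_stat(a, b), abs=1e-9)
        lo, hi = ci_mean_axial(a, seed=0)
        nlo, nhi = ci_mean_axial(na, seed=0)
        assert nlo == pytest.approx(-hi, abs=1e-6)
        assert nhi == pytest.approx(-lo, abs=1e-6)
        assert summarize(a).chirality == "CW"
        assert summarize(na).chirality == "CCW"


class TestCIAndOneSampleTest:
    def test_tight_sample_gives_tight_interval(self):
        s = generate_angle_sample(200, 15.0, 1e8, seed=1)
        lo, hi = ci_mean_axial(s)
        assert hi - lo < 0.05
        assert lo <= 15.0 + 1e-2 and hi >= 15.0 - 1e-2

    def test_mean_always_inside_interval(self):
        for seed in range(5):
            s = generate_angle_sample(80, -10.0, 2.0, seed=seed)
            lo, hi = ci_mean_axial(s)
            assert lo <= circular_mean_axial(s) <= hi

    def test_bootstrap_path_small_n(self):
        s = generate_angle_sample(15, 5.0, 8.0, seed=2)
        lo, hi = ci_mean_axial(s, seed=0)
        assert lo < circular_mean_axial(s) < hi
        # seeded bootstrap is reproducible
        assert ci_mean_axial(s, seed=0) == ci_mean_axial(s, seed=0)

    def test_not_rejected_when_mu0_is_the_mean(self):
        s = generate_angle_sample(50, 0.0, 1.0, seed=4)
        res = one_sample_mean_test(s, mu0_deg=circular_mean_axial(s))
        assert not res.reject

    def test_degenerate_sample_rejects_zero(self):
        s = AngleSample("x", np.full(12, 5.0))
        assert one_sample_mean_test(s, mu0_deg=0.0).reject


class TestWatsonU2:
    def test_identical_point_masses_give_zero(self):
        a = AngleSample("a", np.full(10, 30.0))
        b = AngleSample("b", np.full(10, 30.0))
        assert watson_u2_stat(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_input_validation(self):
        a = generate_angle_sample(20, 0, 2, seed=0)
        small = generate_angle_sample(5, 0, 2, seed=1)
        with pytest.raises(ValueError):
            watson_u2_test(a, small)
        with pytest.raises(ValueError):
            watson_u2_test(a, a, n_perm=50)

    def test_seeded_p_value_reproducible(self):
        a = generate_angle_sample(40, -5, 4, seed=0, label="a")
        b = generate_angle_sample(40, 10, 4, seed=1, label="b")
        r1 = watson_u2_test(a, b, n_perm=999, seed=5)
        r2 = watson_u2_test(a, b, n_perm=999, seed=5)
        assert r1.p_value == r2.p_value and r1.u2 == r2.u2

    def test_detects_clear_shift(self):
        a = generate_angle_sample(300, -8, 6, seed=0)
        b = generate_angle_sample(300, 22, 6, seed=1)
        res = watson_u2_test(a, b, n_perm=999, seed=0)
        assert res.p_value < 0.01
        asym = watson_u2_test(a, b, method="asymptotic")
        assert asym.p_value < 0.01
        assert asym.u2 == pytest.approx(res.u2)

    def test_permutation_close_to_asymptotic_at_moderate_effect(self):
        a = generate_angle_sample(100, 0, 3, seed=2)
        b = generate_angle_sample(100, 8, 3, seed=3)
        p_perm = watson_u2_test(a, b, n_perm=4999, seed=0).p_value
        p_asym = watson_u2_test(a, b, method="asymptotic").p_value
        assert p_perm == pytest.approx(p_asym, abs=0.05)

    def test_tied_data_statistic_finite_and_symmetric(self):
        a = AngleSample("a", np.repeat([10.0, 20.0, 30.0], 5))
        b = AngleSample("b", np.repeat([10.0, 25.0, 30.0], 5))
        u_ab = watson_u2_stat(a, b)
        u_ba = watson_u2_stat(b, a)
        assert np.isfinite(u_ab) and u_ab >= 0
        assert u_ab == pytest.approx(u_ba, abs=1e-12)


class TestSummaryAndHistogram:
    def test_chirality_calls_by_construction(self):
        cw = generate_angle_sample(600, -8, 6, seed=0)
        assert summarize(cw).chirality == "CW"
        ccw = generate_angle_sample(600, 12, 6, seed=1)
        assert summarize(ccw).chirality == "CCW"

    def test_small_sample_is_indeterminate(self):
        s = AngleSample("x", np.array([5.0, 6.0, 7.0]))
        assert summarize(s).chirality == "indeterminate"
        assert summarize(s).ci95 is None

    def test_kurtosis_increases_with_concentration(self):
        # sharper alignment (larger kappa) gives a more peaked linear
        # angle histogram in the broad-distribution regime relevant to
        # alignment data; beyond kappa ~ 2 the half-circle von Mises
        # tends to a Gaussian and the excess kurtosis decays to 0 again,
        # so monotonicity is only asserted below that
        kurts = [summarize(generate_angle_sample(600, 0, k, seed=13)).kurtosis
                 for k in (0.5, 1.0, 2.0)]
        assert kurts[0] < kurts[1] < kurts[2]

    def test_single_bin_histogram(self):
        t = frequency_distribution(AngleSample("x", np.full(4, 10.0)), 10.0)
        assert t["count"].sum() == 4
        assert t["count"].max() == 4
        row = t[t["count"] == 4].iloc[0]
        assert row.bin_left_deg < 10.0 <= row.bin_right_deg

    def test_counts_conserved(self):
        s = generate_angle_sample(1234, 3, 2, seed=5)
        t = frequency_distribution(s, 15.0)
        assert t["count"].sum() == s.n

    def test_invalid_bin_width(self):
        s = generate_angle_sample(10, 0, 1, seed=0)
        with pytest.raises(ValueError):
            frequency_distribution(s, 7.0)

    def test_uniform_sample_fills_bins_evenly(self):
        s = generate_angle_sample(18_000, 0.0, 0.0, seed=21)
        t = frequency_distribution(s, 10.0)
        expected = 1000.0
        sigma = np.sqrt(expected)
        assert np.all(np.abs(t["count"] - expected) < 4 * sigma)
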