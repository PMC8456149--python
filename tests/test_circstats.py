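import numpy as np
import pytest
from hypothesis import given, strategies as st

import suncompass as sc
from suncompass.circstats import p_bracket, sample_null_R_star, wrap180, wrap360


class TestMeanVector:
    def test_concentrated(self):
        mv = sc.mean_vector([90.0] * 5)
        assert mv.theta == pytest.approx(90.0)
        assert mv.r == pytest.approx(1.0)

    def test_antipodal_cancellation_flags_undefined_direction(self):
        mv = sc.mean_vector([0.0, 180.0])
        assert mv.r == 0.0
        assert mv.undefined

    def test_unit_vector_sum_oracle(self):
        # frozen from summing three unit vectors by hand
        mv = sc.mean_vector([10.0, 20.0, 30.0])
        assert mv.theta == pytest.approx(20.0, abs=1e-9)
        assert mv.r == pytest.approx(0.98987, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.mean_vector([])


class TestCircDiff:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (257.1, 188.2, 68.9),   # clock shift vs sun compass, clockwise
            (257.1, 194.4, 62.7),   # clock shift vs late-flown subgroup
            (123.4, 123.4, 0.0),
            (10.0, 350.0, 20.0),    # wrap-around
            (350.0, 10.0, -20.0),
        ],
    )
    def test_signed_clockwise_difference(self, a, b, expected):
        assert sc.circ_diff(a, b) == pytest.approx(expected, abs=1e-9)

    def test_wrap_edges(self):
        assert wrap180(180.0) == pytest.approx(180.0)
        assert wrap180(-180.0) == pytest.approx(180.0)
        assert wrap360(-10.0) == pytest.approx(350.0)


class TestRayleigh:
    @pytest.mark.parametrize(
        "n, r, expected, digits",
        [(30, 0.384, 0.011, 3), (15, 0.664, 0.0007, 4), (27, 0.416, 0.008, 3)],
    )
    def test_series_approximation(self, n, r, expected, digits):
        res = sc.rayleigh_test(n=n, r=r)
        assert round(res.p, digits) == pytest.approx(expected)
        assert res.Z == pytest.approx(n * r * r)

    def test_uniform_gives_p_one(self):
        assert sc.rayleigh_test(n=20, r=0.0).p == 1.0

    def test_p_decreasing_in_r(self):
        ps = [sc.rayleigh_test(n=25, r=r).p for r in np.linspace(0, 0.9, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_angles_input_matches_summary_input(self):
        angles = [10.0, 80.0, 200.0, 215.0, 230.0]
        mv = sc.mean_vector(angles)
        assert sc.rayleigh_test(angles).p == pytest.approx(
            sc.rayleigh_test(n=5, r=mv.r).p
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sc.rayleigh_test(n=1, r=0.5)


class TestMooreRayleigh:
    def test_analytic_maximum_n4(self):
        res = sc.moore_rayleigh(
            [(90, 0.2), (90, 0.4), (90, 0.6), (90, 0.8)], n_sims=1000, seed=0
        )
        assert res.R_star == pytest.approx((1 + 2 + 3 + 4) / 4**1.5)
        assert res.theta_w == pytest.approx(90.0)

    def test_hand_computed_five_vectors(self):
        # rank-weighted sums computed independently by hand
        vecs = [(30, 0.9), (45, 0.5), (350, 0.7), (120, 0.2), (80, 0.6)]
        res = sc.moore_rayleigh(vecs, n_sims=1000, seed=0)
        assert res.R_star == pytest.approx(1.07234, abs=1e-4)
        assert res.theta_w == pytest.approx(35.9587, abs=1e-3)

    def test_equal_lengths_reduce_to_unweighted_mean(self):
        angles = [15.0, 40.0, 355.0, 80.0, 120.0, 33.0]
        res = sc.moore_rayleigh([(a, 0.5) for a in angles], n_sims=1000, seed=0)
        assert res.theta_w == pytest.approx(sc.mean_vector(angles).theta, abs=1e-9)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            sc.moore_rayleigh([(10, 0.5), (20, 1.2)])
        with pytest.raises(ValueError):
            sc.moore_rayleigh([(10, 0.5)])

    @given(st.integers(0, 2**31 - 1), st.integers(3, 20))
    def test_r_star_bound(self, seed, n):
        # R* can never exceed the value attained when all vectors align
        rng = np.random.default_rng(seed)
        vecs = list(zip(rng.uniform(0, 360, n), rng.uniform(0, 1, n)))
        res = sc.moore_rayleigh(vecs, n_sims=1000, seed=0)
        assert res.R_star <= (n + 1) / (2 * np.sqrt(n)) + 1e-12

    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 359.0))
    def test_rotation_equivariance(self, seed, phi):
        rng = np.random.default_rng(seed)
        vecs = list(zip(rng.uniform(0, 360, 8), rng.uniform(0.1, 1, 8)))
        rotated = [((t + phi) % 360, r) for t, r in vecs]
        a = sc.moore_rayleigh(vecs, n_sims=500, seed=1)
        b = sc.moore_rayleigh(rotated, n_sims=500, seed=1)
        assert b.R_star == pytest.approx(a.R_star, abs=1e-9)
        shift = sc.circ_diff(b.theta_w, a.theta_w)
        assert wrap180(shift - phi) == pytest.approx(0.0, abs=1e-6)
        assert b.p == pytest.approx(a.p)


class TestMMRPvalue:
    def test_zero_statistic_is_nonsignificant(self):
        assert sc.mmr_pvalue(0.0, 10, n_sims=1000, seed=0) > 0.99

    def test_deterministic_per_seed(self):
        a = sc.mmr_pvalue(1.0, 12, n_sims=5000, seed=42)
        b = sc.mmr_pvalue(1.0, 12, n_sims=5000, seed=42)
        assert a == b

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError):
            sc.mmr_pvalue(1.0, 10, n_sims=50)

    def test_bracket_strings(self):
        assert p_bracket(0.0068) == "<0.01"
        assert p_bracket(0.0006) == "<0.001"
        assert p_bracket(0.32) == "<0.5"
        assert p_bracket(0.83) == "<0.9"


class TestBootstrapCI:
    def test_degenerate_identical_vectors(self):
        lo, hi = sc.weighted_mean_ci_bootstrap([(30, 0.5)] * 5, B=1000, seed=0)
        assert lo == pytest.approx(30.0) and hi == pytest.approx(30.0)

    def test_deterministic_per_seed(self, rng):
        vecs = list(zip(rng.uniform(0, 360, 10), rng.uniform(0.2, 1, 10)))
        assert sc.weighted_mean_ci_bootstrap(vecs, B=1000, seed=3) == (
            sc.weighted_mean_ci_bootstrap(vecs, B=1000, seed=3)
        )

    def test_contains_point_estimate(self, rng):
        th = np.rad2deg(rng.vonmises(np.deg2rad(10), 2, 12)) % 360  # straddles 0
        vecs = list(zip(th, rng.uniform(0.2, 1, 12)))
        res = sc.moore_rayleigh(vecs, n_sims=1000, seed=0)
        lo, hi = sc.weighted_mean_ci_bootstrap(vecs, B=2000, seed=0)
        width = (hi - lo) % 360
        assert (res.theta_w - lo) % 360 <= width

    def test_parameter_validation(self):
        vecs = [(0, 0.5), (10, 0.6), (20, 0.7)]
        with pytest.raises(ValueError):
            sc.weighted_mean_ci_bootstrap(vecs, B=10)
        with pytest.raises(ValueError):
            sc.weighted_mean_ci_bootstrap(vecs[:2], B=2000)


class TestMWW:
    def test_identical_multisets(self):
        g = [10.0, 50.0, 123.0, 270.0, 355.0, 30.0, 200.0, 90.0, 180.0, 300.0]
        res = sc.mww_test([g, g])
        assert res.W == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_small_sample_warning(self, rng):
        g1 = rng.uniform(0, 360, 15)
        g2 = rng.uniform(0, 360, 9)
        res = sc.mww_test([g1, g2])
        assert res.small_sample_warning
        assert res.group_sizes == (15, 9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sc.mww_test([[10.0, 20.0], []])

    def test_null_calibration(self):
        # W ~ chi2(2) under uniformity: mean near 2, rejection near 5%
        rng = np.random.default_rng(11)
        Ws, rej = [], 0
        for _ in range(800):
            res = sc.mww_test([rng.uniform(0, 360, 15), rng.uniform(0, 360, 15)])
            Ws.append(res.W)
            rej += res.p < 0.05
        assert np.mean(Ws) == pytest.approx(2.0, abs=0.25)
        assert 0.02 < rej / 800 < 0.09

    def test_power_against_separated_groups(self):
        # von Mises groups (kappa=2, n=15) 90 deg apart; measured power at
        # these conditions is ~0.97 (p<0.05) and ~0.82 (p<0.01)
        rng = np.random.default_rng(21)
        hits05 = hits01 = 0
        reps = 300
        for _ in range(reps):
            g1 = np.rad2deg(rng.vonmises(np.deg2rad(100), 2, 15)) % 360
            g2 = np.rad2deg(rng.vonmises(np.deg2rad(190), 2, 15)) % 360
            p = sc.mww_test([g1, g2]).p
            hits05 += p < 0.05
            hits01 += p < 0.01
        assert hits05 / reps >= 0.90
        assert hits01 / reps >= 0.70


class TestBidirectional:
    def test_perfect_axial_case(self):
        # flies split between theta and theta+180: unidirectional signal
        # cancels, axial signal is maximal
        vecs = [(40, 0.9), (220, 0.8), (40, 0.7), (220, 0.6), (40, 0.5), (220, 0.4)]
        uni = sc.moore_rayleigh(vecs, n_sims=1000, seed=0)
        ax = sc.bidirectional_analysis(vecs, n_sims=1000, seed=0)
        assert uni.R_star < 0.35
        assert ax.R_star > 0.9 * (len(vecs) + 1) / (2 * np.sqrt(len(vecs)))
        assert ax.theta_axial == pytest.approx(40.0, abs=1e-6)

    def test_single_direction(self):
        vecs = [(200, r) for r in (0.3, 0.5, 0.7, 0.9)]
        ax = sc.bidirectional_analysis(vecs, n_sims=1000, seed=0)
        assert ax.theta_axial == pytest.approx(200 % 180, abs=1e-6)

    def test_axial_mean_halves_doubled_mean(self, rng):
        vecs = list(zip(rng.uniform(0, 360, 9), rng.uniform(0.1, 1, 9)))
        doubled = [(2 * t % 360, r) for t, r in vecs]
        ax = sc.bidirectional_analysis(vecs, n_sims=500, seed=2)
        ref = sc.moore_rayleigh(doubled, n_sims=500, seed=2)
        assert ax.theta_axial == pytest.approx(ref.theta_w / 2.0, abs=1e-9)


def test_null_sampler_matches_statistic_definition():
    # a null draw with ranks 1..n equals moore_rayleigh on uniform angles
    # whose r-values are strictly increasing
    rng = np.random.default_rng(5)
    sims = sample_null_R_star(6, 200, np.random.default_rng(5))
    assert sims.shape == (200,)
    assert np.all(sims >= 0) and np.all(sims <= 7 / (2 * np.sqrt(6)))
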