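from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import agreedent as ag
from agreedent.exceptions import CalibrationError, ValidationError


class TestMarginals:
    def test_shapes(self):
        u = ag.marginal_probs("uniform", 8)
        assert np.allclose(u, 1 / 8)
        lo = ag.marginal_probs("skew_low", 8)
        hi = ag.marginal_probs("skew_high", 8)
        assert (np.diff(lo) < 0).all() and (np.diff(hi) > 0).all()
        assert np.allclose(lo, hi[::-1])

    def test_invalid(self):
        with pytest.raises(ValidationError):
            ag.marginal_probs("bimodal", 5)
        with pytest.raises(ValidationError):
            ag.marginal_probs([0.5, 0.6], 2)


class TestSimulator:
    def test_rho_one_identical_raters(self):
        d = ag.SimDesign(n_categories=7, rho=1.0, n_units=30, seed=1)
        codes = ag.simulate_codes(d, reps=5)
        assert (codes == codes[:, :, :1]).all()
        coef, _ = ag.ac_batch(codes, "ordinal")
        assert np.allclose(coef[np.isfinite(coef)], 1.0)

    def test_rho_zero_uniform_ac1_near_zero(self):
        d = ag.SimDesign(n_categories=7, rho=0.0, n_units=200, seed=2)
        coef, _ = ag.ac_batch(ag.simulate_codes(d, reps=1000), "identity")
        assert abs(np.nanmean(coef)) < 0.02

    @pytest.mark.parametrize("marginal", ["uniform", "skew_low", "skew_high"])
    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_marginal_preservation(self, marginal, rho):
        """Per-rater category frequencies follow pi for every rho."""
        d = ag.SimDesign(n_categories=8, n_raters=3, marginal=marginal, rho=rho,
                         n_units=2000, seed=3)
        codes = ag.simulate_codes(d, reps=1)[0]
        pi = d.pi
        for j in range(3):
            obs = np.bincount(codes[:, j], minlength=8)
            p = stats.chisquare(obs, 2000 * pi).pvalue
            assert p > 0.001

    def test_seed_reproducibility(self):
        d = ag.SimDesign(n_categories=7, rho=0.5, n_units=40, seed=11)
        assert (ag.simulate_codes(d, reps=3) == ag.simulate_codes(d, reps=3)).all()

    def test_simulate_ratings_matrix_form(self):
        d = ag.SimDesign(n_categories=5, n_raters=4, rho=0.7, n_units=12, seed=4)
        m = ag.simulate_ratings(d)
        assert (m.n_units, m.n_raters) == (12, 4)
        assert m.n_na == 0


class TestAnalyticLimit:
    def test_expected_ac1_is_rho_squared_uniform(self):
        for rho in (0.0, 0.3, 0.775, 1.0):
            pi = np.full(7, 1 / 7)
            assert ag.expected_ac(rho, pi, "identity") == pytest.approx(rho**2)

    def test_inverse_round_trip(self):
        pi = ag.marginal_probs("skew_low", 8)
        for target in (0.6, 0.75, 0.9):
            rho = ag.rho_for_expected_ac(target, pi, "ordinal")
            assert ag.expected_ac(rho, pi, "ordinal") == pytest.approx(target, abs=1e-12)

    def test_target_below_weighted_chance_baseline_raises(self):
        """With ordinal weights on skewed marginals, independent raters
        already share substantial weighted agreement; targets below that
        baseline are unattainable."""
        pi = ag.marginal_probs("skew_low", 8)
        baseline = ag.expected_ac(0.0, pi, "ordinal")
        assert baseline > 0.3
        with pytest.raises(CalibrationError):
            ag.rho_for_expected_ac(baseline - 0.05, pi, "ordinal")

    def test_monte_carlo_matches_analytic(self):
        for rho in (0.5, 0.775):
            d = ag.SimDesign(n_categories=7, rho=rho, n_units=200, seed=6)
            coef, _ = ag.ac_batch(ag.simulate_codes(d, reps=1000), "identity")
            assert np.nanmean(coef) == pytest.approx(rho**2, abs=0.02)


class TestCalibration:
    def test_uniform_identity_target_recovers_sqrt(self):
        base = ag.SimDesign(n_categories=7, n_raters=9, marginal="uniform",
                            n_units=200, seed=7)
        rho = ag.calibrate_rho(0.6, base, "identity", reps=500)
        assert rho == pytest.approx(np.sqrt(0.6), abs=0.03)

    def test_near_one_target(self):
        base = ag.SimDesign(n_categories=5, n_raters=4, n_units=50, seed=8)
        rho = ag.calibrate_rho(0.99, base, "identity", reps=200)
        assert rho > 0.97

    def test_self_consistency_across_seeds(self):
        rhos = []
        for seed in (21, 22):
            base = ag.SimDesign(n_categories=7, n_raters=9, marginal="skew_low",
                                n_units=150, seed=seed)
            rhos.append(ag.calibrate_rho(0.6, base, "ordinal", reps=400))
        assert abs(rhos[0] - rhos[1]) < 0.03

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            ag.calibrate_rho(1.5, ag.SimDesign(n_categories=5, seed=1))


class TestPower:
    def test_size_of_test_near_alpha(self):
        """When the truth equals the null, rejection rate ~ alpha."""
        base = ag.SimDesign(n_categories=7, n_raters=9, n_units=40, seed=9)
        rho = ag.calibrate_rho(0.4, base, "ordinal", reps=500)
        pw, mc_se, _ = ag.estimate_power(
            replace(base, rho=rho), "ordinal", 0.4, 0.05, reps=2000
        )
        assert pw == pytest.approx(0.05, abs=0.03)

    def test_rho_one_full_power(self):
        d = ag.SimDesign(n_categories=7, n_raters=9, rho=1.0, n_units=5, seed=10)
        pw, _, _ = ag.estimate_power(d, "ordinal", 0.4, 0.05, reps=200)
        assert pw == 1.0

    def test_monotone_in_n(self):
        # rho set so the true AC2 (~0.5) sits above the null 0.4
        rho = ag.rho_for_expected_ac(0.5, np.full(8, 1 / 8), "ordinal")
        base = ag.SimDesign(n_categories=8, n_raters=9, rho=rho, n_units=10, seed=12)
        p10, _, _ = ag.estimate_power(base, "ordinal", 0.4, 0.05, reps=1000)
        p40, _, _ = ag.estimate_power(replace(base, n_units=40), "ordinal", 0.4,
                                      0.05, reps=1000)
        assert p40 >= p10 - 0.02


class TestMinN:
    def test_target_power_zero_gives_first_grid_point(self):
        grid = ag.min_n_for_power(
            conditions=[("uniform", 7)], n_grid=(5, 10), target_power=0.0,
            reps=50, calib_reps=100, seed=1,
        )
        assert grid.min_n[("uniform", 7)] == 5

    def test_reproducible_given_seed(self):
        kw = dict(conditions=[("skew_low", 7)], n_grid=(10, 20), reps=200,
                  calib_reps=200, seed=5)
        a = ag.min_n_for_power(**kw)
        b = ag.min_n_for_power(**kw)
        assert a.power == b.power and a.rho == b.rho and a.min_n == b.min_n

    def test_rep_doubling_stability(self):
        kw = dict(conditions=[("uniform", 8)], seed=3, calib_reps=400)
        a = ag.min_n_for_power(reps=500, **kw)
        b = ag.min_n_for_power(reps=1000, **kw)
        grid = list(a.n_grid)
        ia = grid.index(a.min_n[("uniform", 8)])
        ib = grid.index(b.min_n[("uniform", 8)])
        assert abs(ia - ib) <= 1


class TestBonett:
    def test_study_planning_value(self):
        assert ag.bonett_icc_n(0.8, 9, 0.1, 0.95) == 25

    def test_tighter_halfwidth(self):
        assert ag.bonett_icc_n(0.8, 9, 0.05, 0.95) == 95

    def test_monotone_in_halfwidth(self):
        assert ag.bonett_icc_n(0.8, 9, 0.2) <= ag.bonett_icc_n(0.8, 9, 0.1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ag.bonett_icc_n(1.2, 9, 0.1)
        with pytest.raises(ValueError):
            ag.bonett_icc_n(0.8, 1, 0.1)
        with pytest.raises(ValueError):
            ag.bonett_icc_n(0.8, 9, 0.0)


class TestPrecisionN:
    def test_loose_halfwidth_first_grid_point(self):
        n, _ = ag.precision_n_simulated("ac2", 0.8, 0.5, n_grid=(5, 10), reps=100,
                                        seed=1)
        assert n == 5

    def test_monotone_in_halfwidth(self):
        n_loose, _ = ag.precision_n_simulated(
            "ac1", 0.8, 0.10, n_categories=5, n_raters=6, reps=200, seed=2
        )
        n_tight, _ = ag.precision_n_simulated(
            "ac1", 0.8, 0.05, n_categories=5, n_raters=6, reps=200, seed=2
        )
        assert n_tight is None or n_loose is None or n_tight >= n_loose

    def test_kappa_route_returns_finite_n(self):
        n, diag = ag.precision_n_simulated(
            "kappa", 0.8, 0.1, n_categories=5, n_raters=6, reps=60,
            n_grid=(10, 20, 30, 40, 50), seed=3,
        )
        assert n is not None
        assert 0 < diag["rho"] < 1
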