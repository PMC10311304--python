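"""Mean functions, likelihoods, priors and prior sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dosebayes as db
from dosebayes.model import log_prior_combo, log_prior_mono

LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


class TestHillMean:
    @pytest.mark.parametrize(
        "params,x,expected",
        [
            (dict(E0=100, E1=0, C=1, H=1, sigma=1), 0.0, 100.0),  # zero-dose limit
            (dict(E0=100, E1=0, C=1, H=2, sigma=1), 1.0, 50.0),  # midpoint at x=C
            (dict(E0=100, E1=20, C=0.5, H=1, sigma=1), 1.5, 40.0),  # direct evaluation
        ],
    )
    def test_known_values(self, params, x, expected):
        assert db.hill_mean(db.MonotherapyParams(**params), x) == pytest.approx(
            expected, abs=1e-10
        )

    def test_rejects_bad_doses(self, mono_params):
        with pytest.raises(ValueError):
            db.hill_mean(mono_params, -1.0)
        with pytest.raises(ValueError):
            db.hill_mean(mono_params, np.nan)

    @settings(max_examples=100, deadline=None)
    @given(
        e1_ratio=st.floats(0.0, 1.0),
        c=st.floats(1e-6, 1e6),
        h=st.floats(0.05, 20.0),
    )
    def test_monotone_decreasing_and_bounded(self, e1_ratio, c, h):
        """The curve decreases from E0 towards E1 and never leaves [E1, E0]."""
        p = db.MonotherapyParams(E0=100.0, E1=100.0 * e1_ratio, C=c, H=h, sigma=1.0)
        grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e8, 200)])
        y = db.hill_mean(p, grid)
        assert np.all(np.diff(y) <= 1e-9)
        assert np.all(y <= p.E0 + 1e-9) and np.all(y >= p.E1 - 1e-9)


class TestComboMean:
    def test_base_cell_returns_e0(self, combo_params):
        assert db.combo_mean(combo_params, 0.0, 0.0) == combo_params.E0

    def test_symmetric_unit_example(self):
        p = db.CombinationParams(
            E0=100, E1=0, E2=0, E3=0, C1=1, C2=1, H1=1, H2=1, alpha=1, sigma=1
        )
        assert db.combo_mean(p, 1.0, 1.0) == pytest.approx(25.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.data(),
        x=st.floats(0.0, 1e6),
    )
    def test_reduces_to_hill_on_slices(self, data, x):
        rng_vals = data.draw(
            st.tuples(*(st.floats(0.05, 0.95) for _ in range(3))), label="ratios"
        )
        c1 = data.draw(st.floats(1e-4, 1e4))
        c2 = data.draw(st.floats(1e-4, 1e4))
        h1 = data.draw(st.floats(0.1, 10.0))
        h2 = data.draw(st.floats(0.1, 10.0))
        alpha = data.draw(st.floats(0.05, 20.0))
        p = db.CombinationParams(
            E0=100.0,
            E1=100 * rng_vals[0], E2=100 * rng_vals[1], E3=100 * rng_vals[2],
            C1=c1, C2=c2, H1=h1, H2=h2, alpha=alpha, sigma=1.0,
        )
        expect1 = db.hill_mean(p.drug1(), x)
        expect2 = db.hill_mean(p.drug2(), x)
        assert db.combo_mean(p, x, 0.0) == pytest.approx(expect1, rel=1e-12, abs=1e-9)
        assert db.combo_mean(p, 0.0, x) == pytest.approx(expect2, rel=1e-12, abs=1e-9)

    def test_alpha_only_acts_in_the_interior(self, combo_params):
        p2 = db.CombinationParams(
            **{**combo_params.__dict__, "alpha": combo_params.alpha * 10}
        )
        assert db.combo_mean(combo_params, 1.2, 0.0) == db.combo_mean(p2, 1.2, 0.0)
        assert db.combo_mean(combo_params, 0.0, 0.7) == db.combo_mean(p2, 0.0, 0.7)
        assert db.combo_mean(combo_params, 1.2, 0.7) != db.combo_mean(p2, 1.2, 0.7)

    def test_rejects_negative_dose(self, combo_params):
        with pytest.raises(ValueError):
            db.combo_mean(combo_params, -0.1, 1.0)


class TestLikelihoods:
    def test_zero_residual_single_point(self, mono_params):
        p = db.MonotherapyParams(100, 20, 0.5, 1, 1.0)
        y = db.hill_mean(p, 2.0)
        data = db.DoseResponseDataset([[2.0]], [y])
        assert db.log_likelihood_mono(p, data) == pytest.approx(
            -LOG_SQRT_2PI, abs=1e-12
        )

    def test_additivity_over_identical_points(self, mono_params):
        one = db.DoseResponseDataset([[1.0]], [60.0])
        two = db.DoseResponseDataset([[1.0], [1.0]], [60.0, 60.0])
        assert db.log_likelihood_mono(mono_params, two) == pytest.approx(
            2 * db.log_likelihood_mono(mono_params, one), rel=1e-14
        )

    def test_residual_four_at_scale_two(self):
        p = db.MonotherapyParams(100, 0, 1, 1, 2.0)
        data = db.DoseResponseDataset([[1.0]], [54.0])  # mean is 50, residual 4
        assert db.log_likelihood_mono(p, data) == pytest.approx(
            stats.norm.logpdf(4.0, scale=2.0), abs=1e-12
        )

    def test_combo_reduces_to_mono_when_drug2_absent(self, combo_params):
        doses1 = np.geomspace(0.01, 10, 8)
        rng = np.random.default_rng(0)
        y = rng.normal(80, 5, size=8)
        combo_data = db.DoseResponseDataset(
            np.column_stack([doses1, np.zeros(8)]), y
        )
        mono_data = db.DoseResponseDataset(doses1[:, None], y)
        assert db.log_likelihood_combo(combo_params, combo_data) == pytest.approx(
            db.log_likelihood_mono(combo_params.drug1(), mono_data), rel=1e-14
        )

    def test_combo_matches_bruteforce_normal_sum(self, combo_params):
        doses = np.array([[0.0, 0.0], [1.0, 2.0], [0.5, 0.0]])
        y = np.array([99.0, 60.0, 85.0])
        data = db.DoseResponseDataset(doses, y)
        expected = sum(
            stats.norm.logpdf(
                yi, db.combo_mean(combo_params, x1, x2), combo_params.sigma
            )
            for (x1, x2), yi in zip(doses, y)
        )
        assert db.log_likelihood_combo(combo_params, data) == pytest.approx(
            expected, abs=1e-10
        )


class TestPriors:
    @pytest.mark.parametrize("efficacy_prior", ["uniform", "beta"])
    def test_mono_matches_scipy_factorization(self, efficacy_prior):
        cfg = db.PriorConfig(efficacy_prior=efficacy_prior, delta=1e-4, M_upper=1e4)
        p = db.MonotherapyParams(E0=98.0, E1=30.0, C=2.5, H=1.7, sigma=0.8)
        expected = (
            stats.norm.logpdf(p.E0, cfg.B, math.sqrt(0.03 * cfg.B))
            + (
                stats.uniform.logpdf(p.E1 / p.E0)
                if efficacy_prior == "uniform"
                else stats.beta.logpdf(p.E1 / p.E0, 0.46, 0.58)
            )
            - math.log(p.E0)
            + stats.uniform.logpdf(
                math.log(p.C),
                loc=math.log(cfg.delta),
                scale=math.log(cfg.M_upper) - math.log(cfg.delta),
            )
            + stats.lognorm.logpdf(p.H, 1.0)
            + stats.lognorm.logpdf(p.sigma, 1.0)
        )
        assert log_prior_mono(p, cfg) == pytest.approx(expected, abs=1e-10)

    def test_out_of_support_is_minus_inf_not_an_exception(self):
        cfg = db.PriorConfig(delta=1e-2, M_upper=1e2)
        too_big_c = db.MonotherapyParams(100, 50, 2e2, 1, 1)
        assert log_prior_mono(too_big_c, cfg) == -math.inf

    def test_hill_slope_median_contribution(self):
        """H = 1 contributes the lognormal(0,1) density at its median."""
        cfg = db.PriorConfig()
        p1 = db.MonotherapyParams(100, 50, 1.0, 1.0, 1.0)
        assert stats.lognorm.logpdf(1.0, 1.0) == pytest.approx(-LOG_SQRT_2PI)
        # changing only H away from 1 changes the total by the lognormal ratio
        p2 = db.MonotherapyParams(100, 50, 1.0, 2.0, 1.0)
        delta = log_prior_mono(p2, cfg) - log_prior_mono(p1, cfg)
        assert delta == pytest.approx(
            stats.lognorm.logpdf(2.0, 1.0) - stats.lognorm.logpdf(1.0, 1.0), abs=1e-12
        )

    @pytest.mark.parametrize("efficacy_prior", ["uniform", "beta"])
    def test_combo_matches_scipy_factorization(self, combo_params, efficacy_prior):
        cfg = db.PriorConfig(efficacy_prior=efficacy_prior, delta=1e-4, M_upper=1e4)
        p = combo_params
        ratio_lp = (
            (lambda r: stats.uniform.logpdf(r))
            if efficacy_prior == "uniform"
            else (lambda r: stats.beta.logpdf(r, 0.46, 0.58))
        )
        log_c = lambda c: stats.uniform.logpdf(  # noqa: E731
            math.log(c),
            loc=math.log(cfg.delta),
            scale=math.log(cfg.M_upper) - math.log(cfg.delta),
        )
        expected = (
            stats.norm.logpdf(p.E0, cfg.B, math.sqrt(0.03 * cfg.B))
            + sum(ratio_lp(e / p.E0) - math.log(p.E0) for e in (p.E1, p.E2, p.E3))
            + log_c(p.C1)
            + log_c(p.C2)
            + stats.lognorm.logpdf(p.H1, 1.0)
            + stats.lognorm.logpdf(p.H2, 1.0)
            + stats.lognorm.logpdf(p.alpha, 1.0)
            + stats.lognorm.logpdf(p.sigma, 1.0)
        )
        assert log_prior_combo(p, cfg) == pytest.approx(expected, abs=1e-10)

    def test_invalid_efficacy_level_rejected_by_type(self):
        with pytest.raises(ValueError):
            db.CombinationParams(100, 120, 10, 10, 1, 1, 1, 1, 1, 1)


class TestSamplePrior:
    def test_deterministic_given_seed(self):
        cfg = db.PriorConfig()
        a = db.sample_prior(cfg, "combo", 5, seed=42)
        b = db.sample_prior(cfg, "combo", 5, seed=42)
        assert a == b

    def test_all_draws_valid_with_finite_log_prior(self):
        cfg = db.PriorConfig(efficacy_prior="beta", delta=1e-3, M_upper=1e3)
        for p in db.sample_prior(cfg, "mono", 200, seed=1):
            assert np.isfinite(log_prior_mono(p, cfg))

    def test_beta_lower_tail_mass(self):
        """Empirical mass of E1/E0 below 0.05 matches the Beta(0.46,0.58) CDF."""
        cfg = db.PriorConfig(efficacy_prior="beta")
        draws = db.sample_prior(cfg, "mono", 10_000, seed=5)
        frac = np.mean([p.E1 / p.E0 < 0.05 for p in draws])
        assert frac == pytest.approx(stats.beta.cdf(0.05, 0.46, 0.58), abs=0.02)

    def test_marginals_pass_goodness_of_fit(self):
        """Each sampled marginal matches its analytic prior (K-S at n=10^4)."""
        cfg = db.PriorConfig(delta=1e-3, M_upper=1e3)
        draws = db.sample_prior(cfg, "combo", 10_000, seed=11)
        e0 = np.array([p.E0 for p in draws])
        logc = np.log([p.C1 for p in draws])
        h = np.array([p.H2 for p in draws])
        alpha = np.array([p.alpha for p in draws])
        r3 = np.array([p.E3 / p.E0 for p in draws])
        checks = [
            (e0, stats.norm(cfg.B, math.sqrt(0.03 * cfg.B)).cdf),
            (logc, stats.uniform(math.log(1e-3), math.log(1e6)).cdf),
            (h, lambda x: stats.norm.cdf(np.log(x))),
            (alpha, lambda x: stats.norm.cdf(np.log(x))),
            (r3, stats.uniform.cdf),
        ]
        for sample, cdf in checks:
            assert stats.kstest(sample, cdf).pvalue > 0.001
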