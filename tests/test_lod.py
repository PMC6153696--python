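"""LOD-based imputation: censored-normal fits, RC/ITS/MITS and run-day
variants."""

import numpy as np
import pytest
from scipy import integrate, stats

from metimpute import (
    fit_censored_normal,
    impute_its,
    impute_mean,
    impute_min,
    impute_mits,
    impute_rc,
    rundaywise,
)
from metimpute.lod import conditional_mean_below, CensoredNormalFit

from conftest import make_matrix


class TestConstantFills:
    def test_mean_fill_by_hand(self):
        m = make_matrix(np.array([[1.0], [3.0], [np.nan]]))
        out = impute_mean(m)
        assert out.single()[2, 0] == pytest.approx(2.0)

    def test_min_fill_is_order_statistic(self):
        m = make_matrix(np.array([[3.0], [1.0], [np.nan], [2.0]]))
        out = impute_min(m)
        assert out.single()[2, 0] == 1.0
        assert out.single()[:, 0].min() == 1.0  # min unchanged by min-fill

    def test_complete_input_identity(self, rng):
        m = make_matrix(rng.standard_normal((10, 3)))
        for f in (impute_mean, impute_min):
            assert np.array_equal(f(m).single(), m.values)

    def test_fully_missing_column_rejected(self):
        m = make_matrix(np.array([[np.nan, 1.0], [np.nan, 2.0]]))
        with pytest.raises(ValueError, match="fully missing"):
            impute_mean(m)


class TestCensoredNormalFit:
    def test_parameter_recovery_from_upper_half(self):
        # the MLE at 50% truncation is noisy per draw; its average over
        # replicates recovers the generating N(0,1) parent
        gen = np.random.default_rng(0)
        mus, sigmas = [], []
        for _ in range(8):
            x = gen.standard_normal(50_000)
            fit = fit_censored_normal(
                x[x >= 0], n_missing=int((x < 0).sum()), lod=0.0
            )
            assert fit.converged
            mus.append(fit.mu)
            sigmas.append(fit.sigma)
        assert np.mean(mus) == pytest.approx(0.0, abs=0.03)
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.03)

    def test_matches_independent_optimizer(self):
        # same truncated likelihood maximized along an independent route
        gen = np.random.default_rng(3)
        x = gen.standard_normal(20_000)
        obs = x[x >= 0]
        fit = fit_censored_normal(obs, n_missing=int((x < 0).sum()), lod=0.0)

        def nll(p):
            mu, ls = p
            s = np.exp(ls)
            return -(
                np.sum(stats.norm.logpdf(obs, mu, s))
                - obs.size * stats.norm.logsf(0.0, mu, s)
            )

        from scipy.optimize import minimize

        ref = minimize(nll, [obs.mean(), np.log(obs.std())], method="L-BFGS-B")
        assert fit.mu == pytest.approx(ref.x[0], abs=1e-3)
        assert fit.sigma == pytest.approx(np.exp(ref.x[1]), abs=1e-3)

    def test_no_truncation_reduces_to_moments(self):
        gen = np.random.default_rng(1)
        x = gen.normal(5, 2, size=20_000)
        fit = fit_censored_normal(x, n_missing=0, lod=x.min() - 50)
        assert fit.mu == pytest.approx(x.mean(), abs=0.05)
        assert fit.sigma == pytest.approx(x.std(), abs=0.05)

    def test_loglik_improves_on_moment_start(self):
        gen = np.random.default_rng(2)
        x = gen.standard_normal(2000)
        obs = x[x >= -0.5]
        fit = fit_censored_normal(obs, n_missing=0, lod=-0.5)
        start_ll = float(
            np.sum(stats.norm.logpdf(obs, obs.mean(), obs.std()))
            - obs.size * stats.norm.logsf(-0.5, obs.mean(), obs.std())
        )
        assert fit.loglik >= start_ll - 1e-9

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_censored_normal(np.array([1.0, 1.0, 1.0, 2.0]), 0, 1.0)


class TestConditionalMean:
    def test_standard_normal_at_zero_lod(self):
        fit = CensoredNormalFit(0.0, 1.0, 0.0, 0.0, True, 10, 5)
        # closed form -phi(0)/Phi(0); cross-checked by numerical integration
        closed = conditional_mean_below(fit)
        assert closed == pytest.approx(-0.7979, abs=1e-4)
        numeric = integrate.quad(
            lambda v: v * stats.norm.pdf(v), -np.inf, 0
        )[0] / stats.norm.cdf(0)
        assert closed == pytest.approx(numeric, abs=1e-8)

    def test_conditional_mean_below_lod(self):
        fit = CensoredNormalFit(2.0, 1.5, 1.0, 0.0, True, 10, 5)
        assert conditional_mean_below(fit) < fit.lod

    def test_deep_tail_falls_back_to_lod(self):
        fit = CensoredNormalFit(0.0, 1.0, -40.0, 0.0, True, 10, 5)
        with pytest.warns(UserWarning, match="lower tail"):
            assert conditional_mean_below(fit) == -40.0


def _censored_column_matrix(seed=3, n=400, q=0.3):
    gen = np.random.default_rng(seed)
    x = gen.standard_normal(n)
    y = 0.5 * x + gen.standard_normal(n)
    cut = np.quantile(x, q)
    vals = np.column_stack([np.where(x < cut, np.nan, x), y])
    return make_matrix(vals), x


class TestRcIts:
    def test_rc_fill_is_constant_below_lod(self):
        m, _ = _censored_column_matrix()
        out = impute_rc(m)
        filled = out.single()[m.mask[:, 0], 0]
        assert np.unique(filled).size == 1
        assert filled[0] <= np.nanmin(m.values[:, 0])

    def test_its_draws_below_lod_and_match_rc_mean(self):
        gen = np.random.default_rng(4)
        x = gen.standard_normal(100_000)
        vals = np.column_stack(
            [np.where(x < 0, np.nan, x), gen.standard_normal(100_000)]
        )
        m = make_matrix(vals)
        out = impute_its(m, seed=5)
        draws = out.single()[m.mask[:, 0], 0]
        lod = np.nanmin(m.values[:, 0])
        assert draws.max() <= lod
        # large-sample ITS mean approaches the RC conditional-mean constant
        rc_const = impute_rc(m).single()[m.mask[:, 0], 0][0]
        assert draws.mean() == pytest.approx(rc_const, abs=0.01)

    def test_its_seed_determinism(self):
        m, _ = _censored_column_matrix()
        a = impute_its(m, seed=6).single()
        b = impute_its(m, seed=6).single()
        assert np.array_equal(a, b)

    def test_observed_cells_never_altered(self):
        m, _ = _censored_column_matrix()
        for out in (impute_rc(m), impute_its(m, seed=7), impute_mits(m, seed=8)):
            for f in out.fills:
                assert np.array_equal(f[~m.mask], m.values[~m.mask])


class TestMits:
    def test_default_twenty_fills_vary_only_on_masked_cells(self):
        m, _ = _censored_column_matrix()
        out = impute_mits(m, seed=9)
        assert out.m == 20
        stacked = np.stack(out.fills)
        assert (np.ptp(stacked, axis=0)[~m.mask] == 0).all()
        assert (np.ptp(stacked, axis=0)[m.mask] > 0).any()

    def test_m_equals_one_matches_its_distributionally(self):
        m, _ = _censored_column_matrix()
        out = impute_mits(m, m_imputations=1, seed=10)
        assert out.m == 1
        lod = np.nanmin(m.values[:, 0])
        assert out.single()[m.mask[:, 0], 0].max() <= lod

    def test_between_fill_variance_matches_truncated_variance(self):
        # each masked cell's fills are iid draws from the fitted truncated part
        gen = np.random.default_rng(11)
        x = gen.standard_normal(20_000)
        vals = np.column_stack(
            [np.where(x < 0, np.nan, x), gen.standard_normal(20_000)]
        )
        m = make_matrix(vals)
        out = impute_mits(m, m_imputations=200, seed=12)
        stacked = np.stack(out.fills)[:, m.mask[:, 0], 0]
        # truncated N(0,1) below 0: var = 1 - mills*(mills - 0) with
        # mills = phi(0)/Phi(0)
        mills = stats.norm.pdf(0) / stats.norm.cdf(0)
        expected = 1 - mills * mills
        assert np.mean(stacked.var(axis=0, ddof=1)) == pytest.approx(
            expected, rel=0.1
        )


class TestRundaywise:
    def _two_day_matrix(self, shift=2.0, n_day=40, seed=13):
        gen = np.random.default_rng(seed)
        a = gen.standard_normal(n_day)
        b = gen.standard_normal(n_day) + shift
        x = np.r_[a, b]
        cut_a, cut_b = np.quantile(a, 0.3), np.quantile(b, 0.3)
        cuts = np.r_[np.full(n_day, cut_a), np.full(n_day, cut_b)]
        vals = np.column_stack(
            [np.where(x < cuts, np.nan, x), gen.standard_normal(2 * n_day)]
        )
        runday = np.repeat(["D1", "D2"], n_day)
        return make_matrix(vals, runday=runday)

    def test_day_specific_rc_constants_differ(self):
        m = self._two_day_matrix()
        out = rundaywise(m, base="RC")
        d1 = out.fills[0][(m.runday == "D1") & m.mask[:, 0], 0]
        d2 = out.fills[0][(m.runday == "D2") & m.mask[:, 0], 0]
        assert np.unique(d1).size == 1 and np.unique(d2).size == 1
        assert d1[0] != d2[0]

    def test_single_runday_collapses_to_global(self):
        m, _ = _censored_column_matrix(seed=14)
        out_r = rundaywise(m, base="RC")
        out_g = impute_rc(m)
        np.testing.assert_allclose(out_r.fills[0], out_g.single())

    def test_small_days_fall_back(self):
        # 3 days of 8 samples: below the 17-observation rule everywhere
        gen = np.random.default_rng(15)
        x = gen.standard_normal(24)
        vals = np.column_stack([np.where(x < -0.3, np.nan, x), x + 0.1])
        m = make_matrix(vals, runday=np.repeat(["D1", "D2", "D3"], 8))
        with pytest.warns(UserWarning):
            out = rundaywise(m, base="RC")
        filled = out.fills[0][m.mask[:, 0], 0]
        obs_mean = np.nanmean(m.values[:, 0])
        np.testing.assert_allclose(filled, obs_mean)

    def test_mits_r_produces_m_complete_fills(self):
        m = self._two_day_matrix(seed=16)
        out = rundaywise(m, base="MITS", m_imputations=5, seed=17)
        assert out.m == 5
        for f in out.fills:
            assert not np.isnan(f).any()
            assert np.array_equal(f[~m.mask], m.values[~m.mask])
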