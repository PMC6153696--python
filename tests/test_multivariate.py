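"""Chained-equations and KNN imputation, including the brute-force KNN
oracle."""

import numpy as np
import pytest

from metimpute import KnnConfig, ice_impute, knn_impute, mice_avg, mice_impute

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent brute-force KNN oracle (direct transcription of the method
# definition; kept deliberately naive and separate from the implementation)


def _oracle_standardize(values, mask):
    z = values.copy()
    for j in range(values.shape[1]):
        obs = values[~mask[:, j], j]
        sd = obs.std() if obs.std() > 0 else 1.0
        z[:, j] = (values[:, j] - obs.mean()) / sd
    return z


def _oracle_dist(a, b, p_full):
    shared = [t for t in range(len(a))
              if not np.isnan(a[t]) and not np.isnan(b[t])]
    if not shared:
        return np.inf
    ss = sum((a[t] - b[t]) ** 2 for t in shared)
    return np.sqrt(p_full / len(shared) * ss)


def _oracle_knn_obs(values, mask, k):
    z = _oracle_standardize(values, mask)
    n, p = values.shape
    out = values.copy()
    for j in range(p):
        feats = [c for c in range(p) if c != j]
        for i in range(n):
            if not mask[i, j]:
                continue
            cands = []
            for r in range(n):
                if mask[r, j]:
                    continue
                d = _oracle_dist(z[i, feats], z[r, feats], len(feats))
                if np.isfinite(d):
                    cands.append((d, r))
            cands.sort()
            top = cands[:k]
            w = np.array([np.exp(-d) for d, _ in top])
            v = np.array([z[r, j] for _, r in top])
            obs = values[~mask[:, j], j]
            sd = obs.std() if obs.std() > 0 else 1.0
            out[i, j] = (w @ v) / w.sum() * sd + obs.mean()
    return out


class TestKnn:
    def test_zero_distance_duplicate_row(self):
        vals = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [5.0, 9.0, 4.0],
             [0.0, 1.0, 6.0]]
        )
        out = knn_impute(make_matrix(vals), KnnConfig(mode="obs", k=1))
        assert out.single()[1, 2] == pytest.approx(3.0)

    @pytest.mark.parametrize("k", [1, 3, 5, 10, 20])
    def test_obs_matches_bruteforce_oracle(self, k):
        gen = np.random.default_rng(20 + k)
        vals = gen.standard_normal((30, 10))
        mask = gen.random((30, 10)) < 0.2
        vals[mask] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, KnnConfig(mode="obs", k=k))
        oracle = _oracle_knn_obs(m.values.copy(), mask, k)
        np.testing.assert_allclose(out.single(), np.where(mask, oracle, vals),
                                   atol=1e-10)

    def test_obs_sel_equals_obs_when_all_columns_selected(self):
        # <= 10 non-target columns, all pairwise |rho| >= 0.2
        gen = np.random.default_rng(31)
        base = gen.standard_normal((80, 1))
        vals = 0.8 * base + 0.3 * gen.standard_normal((80, 6))
        mask = gen.random((80, 6)) < 0.2
        vals[mask] = np.nan
        m = make_matrix(vals)
        a = knn_impute(m, KnnConfig(mode="obs", k=5))
        b = knn_impute(m, KnnConfig(mode="obs-sel", k=5, sel_min=5, sel_max=10))
        np.testing.assert_allclose(a.single(), b.single())

    def test_var_mode_uses_column_neighbors(self):
        # X1 duplicates X0; the masked X0 cell should come from X1 (up to the
        # small shift the per-column observed-moment standardization causes)
        x = np.linspace(0, 1, 12)
        vals = np.column_stack([x, x, np.linspace(5, -5, 12)])
        vals[3, 0] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, KnnConfig(mode="var", k=1))
        assert out.single()[3, 0] == pytest.approx(x[3], abs=0.05)
        # far from the anti-correlated third column's value at that row
        assert abs(out.single()[3, 0] - vals[3, 2]) > 1.0

    def test_weighted_average_hand_value(self):
        # neighbors at distances {0,1,2} with standardized values {1,2,3}:
        # (1 + e^-1*2 + e^-2*3)/(1 + e^-1 + e^-2)
        d = np.array([0.0, 1.0, 2.0])
        v = np.array([1.0, 2.0, 3.0])
        w = np.exp(-d)
        expected = (1 + np.e**-1 * 2 + np.e**-2 * 3) / (1 + np.e**-1 + np.e**-2)
        assert (w @ v) / w.sum() == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.4248, abs=1e-4)

    def test_observed_cells_invariant_and_output_complete(self):
        gen = np.random.default_rng(33)
        vals = gen.standard_normal((25, 6))
        mask = gen.random((25, 6)) < 0.25
        vals[mask] = np.nan
        m = make_matrix(vals)
        for mode in ("var", "obs", "obs-sel"):
            out = knn_impute(m, KnnConfig(mode=mode, k=3))
            f = out.single()
            assert not np.isnan(f).any()
            assert np.array_equal(f[~mask], m.values[~mask])


class TestIce:
    def test_complete_matrix_unchanged(self, rng):
        m = make_matrix(rng.standard_normal((20, 4)))
        out = ice_impute(m, model="norm", seed=1)
        assert np.array_equal(out.single(), m.values)

    def test_pmm_fills_are_observed_donor_values(self, random_incomplete):
        m = random_incomplete
        out = ice_impute(m, model="pmm", seed=2)
        f = out.single()
        for j in range(m.n_metabolites):
            obs = set(np.round(m.observed(j), 12))
            for v in f[m.mask[:, j], j]:
                assert round(v, 12) in obs

    def test_slope_recovery_under_mar(self):
        # bivariate normal rho=0.8, 30% MAR on one column driven by the other
        gen = np.random.default_rng(3)
        n = 5000
        x = gen.standard_normal(n)
        y = 0.8 * x + 0.6 * gen.standard_normal(n)
        miss = gen.random(n) < np.clip(0.6 - 0.3 * x, 0, 1)  # MAR via x
        vals = np.column_stack([x, np.where(miss, np.nan, y)])
        m = make_matrix(vals)
        out = ice_impute(m, model="norm", seed=4)
        f = out.single()
        slope, intercept = np.polyfit(f[:, 0], f[:, 1], 1)
        resid = f[:, 1] - slope * f[:, 0] - intercept
        se = np.sqrt(resid.var() / (n * f[:, 0].var()))
        assert abs(slope - 0.8) < 3 * se

    def test_adjr_runs_and_respects_mask(self, random_incomplete):
        out = ice_impute(random_incomplete, model="adjR", seed=5)
        f = out.single()
        m = random_incomplete
        assert np.array_equal(f[~m.mask], m.values[~m.mask])

    def test_no_predictor_passes_screen_mean_imputes(self, rng):
        vals = rng.standard_normal((40, 2))
        vals[:8, 0] = np.nan
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="screening"):
            out = ice_impute(m, model="norm", predictor_min_corr=0.999, seed=6)
        np.testing.assert_allclose(
            out.single()[:8, 0], np.nanmean(m.values[:, 0])
        )


class TestMice:
    def test_default_m_and_mask_contract(self, random_incomplete):
        m = random_incomplete
        out = mice_impute(m, model="norm", seed=7)
        assert out.m == 20
        stacked = np.stack(out.fills)
        assert (np.ptp(stacked, axis=0)[~m.mask] == 0).all()

    def test_m_equals_one_is_a_single_chain(self, random_incomplete):
        out = mice_impute(random_incomplete, model="pmm", m_imputations=1,
                          seed=8)
        assert out.m == 1

    def test_mice_avg_is_cellwise_mean(self, random_incomplete):
        m = random_incomplete
        multi = mice_impute(m, model="norm", m_imputations=6, seed=9)
        avg = mice_avg(m, model="norm", m_imputations=6, seed=9)
        np.testing.assert_allclose(
            avg.single()[m.mask], np.mean(multi.fills, axis=0)[m.mask]
        )
        assert np.array_equal(avg.single()[~m.mask], m.values[~m.mask])

    def test_averaging_shrinks_cell_variability(self, random_incomplete):
        # repeated MICE-avg fills vary less than repeated single ICE fills
        m = random_incomplete
        cell = tuple(np.argwhere(m.mask)[0])
        singles = [
            ice_impute(m, model="norm", seed=100 + t).single()[cell]
            for t in range(20)
        ]
        avgs = [
            mice_avg(m, model="norm", m_imputations=10,
                     seed=200 + t).single()[cell]
            for t in range(20)
        ]
        assert np.var(avgs) < np.var(singles)
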