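"""Statistical layer: ANOVA vs independent oracles, sphericity, contrasts,
BH adjustment, mixed model, ICC, BIC Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fracatten.stats import (
    anova_f_within,
    bh_adjust,
    bic_bayes_factor,
    fit_random_intercept_lmm,
    gg_epsilon,
    icc,
    mauchly_test,
    paired_contrast,
    rm_anova_2x3,
)


def brute_force_rm_anova(cube):
    """Projection-matrix oracle: explicit design matrices for every stratum
    of the fully-within two-factor decomposition, SS via projections."""
    s, a, b = cube.shape
    y = cube.reshape(-1)
    n = len(y)
    subj = np.repeat(np.arange(s), a * b)
    fa = np.tile(np.repeat(np.arange(a), b), s)
    fb = np.tile(np.arange(b), s * a)

    def proj(*factors):
        cols = []
        combos = {}
        for i in range(n):
            key = tuple(f[i] for f in factors)
            combos.setdefault(key, len(combos))
        Z = np.zeros((n, len(combos)))
        for i in range(n):
            Z[i, combos[tuple(f[i] for f in factors)]] = 1.0
        return Z @ np.linalg.pinv(Z)

    P1 = np.full((n, n), 1.0 / n)
    Ps, Pa, Pb = proj(subj), proj(fa), proj(fb)
    Pab, Psa, Psb = proj(fa, fb), proj(subj, fa), proj(subj, fb)
    ss = lambda P, Q: float(y @ (P - Q) @ y)
    out = {
        "A": ss(Pa, P1), "B": ss(Pb, P1),
        "AB": float(y @ (Pab - Pa - Pb + P1) @ y),
        "AS": float(y @ (Psa - Ps - Pa + P1) @ y),
        "BS": float(y @ (Psb - Ps - Pb + P1) @ y),
    }
    out["ABS"] = float(
        y @ (np.eye(n) - Pab - Psa - Psb + Pa + Pb + Ps - P1) @ y)
    return out


def cube_to_long(cube):
    s, a, b = cube.shape
    rows = [(f"S{i}", f"A{j}", float(k), cube[i, j, k])
            for i in range(s) for j in range(a) for k in range(b)]
    return pd.DataFrame(rows, columns=["participant", "production", "soa",
                                       "value"])


class TestRmAnova:
    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(5)
        cube = rng.normal(size=(5, 2, 3)) + rng.normal(size=(5, 1, 1))
        oracle = brute_force_rm_anova(cube)
        res = rm_anova_2x3(cube_to_long(cube))
        assert res.effects["production"].ss_effect == pytest.approx(
            oracle["A"], abs=1e-8)
        assert res.effects["soa"].ss_effect == pytest.approx(
            oracle["B"], abs=1e-8)
        assert res.effects["interaction"].ss_effect == pytest.approx(
            oracle["AB"], abs=1e-8)
        assert res.effects["production"].ss_error == pytest.approx(
            oracle["AS"], abs=1e-8)
        assert res.effects["soa"].ss_error == pytest.approx(
            oracle["BS"], abs=1e-8)
        assert res.effects["interaction"].ss_error == pytest.approx(
            oracle["ABS"], abs=1e-8)

    def test_matches_pingouin(self, alpha_long_table):
        pg = pytest.importorskip("pingouin")
        res = rm_anova_2x3(alpha_long_table)
        ref = pg.rm_anova(data=alpha_long_table, dv="value",
                          within=["production", "soa"], subject="participant",
                          detailed=True).set_index("Source")
        assert res.effects["production"].f == pytest.approx(
            ref.loc["production", "F"], rel=1e-9)
        assert res.effects["soa"].f == pytest.approx(
            ref.loc["soa", "F"], rel=1e-9)
        assert res.effects["soa"].gg_epsilon == pytest.approx(
            ref.loc["soa", "eps"], rel=1e-6)

    def test_two_level_factor_f_equals_squared_paired_t(self, alpha_long_table):
        res = rm_anova_2x3(alpha_long_table)
        marg = alpha_long_table.groupby(["participant", "production"],
                                        as_index=False)["value"].mean()
        x = marg[marg.production == "MA"].sort_values("participant")["value"]
        y = marg[marg.production == "MO"].sort_values("participant")["value"]
        t = sps.ttest_rel(x, y)
        assert res.effects["production"].f == pytest.approx(
            t.statistic**2, rel=1e-9)
        assert res.effects["production"].gg_epsilon == 1.0

    def test_pure_additive_model_gives_eta_one(self):
        subj = np.arange(5)[:, None, None] * 1.0
        eff = np.array([0.0, 1.0])[None, :, None]
        cube = np.broadcast_to(subj + eff, (5, 2, 3)).copy()
        cube += np.array([0.0, 0.5, 1.0])[None, None, :]
        res = rm_anova_2x3(cube_to_long(cube))
        assert res.effects["production"].partial_eta_sq == pytest.approx(1.0)
        assert res.effects["soa"].partial_eta_sq == pytest.approx(1.0)

    def test_total_ss_conservation(self, alpha_long_table):
        res = rm_anova_2x3(alpha_long_table)
        parts = res.ss_subjects + sum(
            e.ss_effect + e.ss_error for e in res.effects.values())
        assert parts == pytest.approx(res.ss_total, abs=1e-8)

    def test_missing_cell_rejected(self, alpha_long_table):
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_2x3(alpha_long_table.iloc[:-1])

    def test_fast_f_path_agrees_with_full_decomposition(self, alpha_long_table):
        res = rm_anova_2x3(alpha_long_table)
        piv = alpha_long_table.pivot_table(
            index="participant", columns=["production", "soa"], values="value")
        cube = piv.to_numpy().reshape(len(piv), 2, 3)
        fa, fb, fab = anova_f_within(cube)
        assert fa == pytest.approx(res.effects["production"].f, rel=1e-12)
        assert fb == pytest.approx(res.effects["soa"].f, rel=1e-12)
        assert fab == pytest.approx(res.effects["interaction"].f, rel=1e-12)


class TestSphericity:
    def test_compound_symmetry_gives_epsilon_one(self):
        S = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_two_conditions_epsilon_one(self):
        assert gg_epsilon(np.array([[1.0, 0.2], [0.2, 2.0]])) == 1.0

    def test_lower_bound_for_rank_deficient_contrast_covariance(self):
        # all contrast variance on a single direction → ε = 1/(k−1)
        v = np.array([1.0, -1.0, 0.0])
        S = np.outer(v, v)
        assert gg_epsilon(S) == pytest.approx(1.0 / 2)

    def test_mauchly_matches_pingouin(self, alpha_long_table):
        pg = pytest.importorskip("pingouin")
        marg = alpha_long_table.groupby(["participant", "soa"],
                                        as_index=False)["value"].mean()
        piv = marg.pivot(index="participant", columns="soa", values="value")
        w, p = mauchly_test(piv.to_numpy())
        ref = pg.sphericity(marg, dv="value", within="soa",
                            subject="participant")
        assert w == pytest.approx(ref.W, rel=1e-9)
        assert p == pytest.approx(ref.pval, rel=1e-9)


class TestPairedContrast:
    def test_hand_worked_five_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.5, 2.5, 2.0, 3.0, 4.0])
        # diffs: 0.5 −0.5 1.0 1.0 1.0 → mean 0.6, sd 0.65192...
        r = paired_contrast(x, y)
        d = x - y
        assert r.t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(5)))
        assert r.df == 4
        ref = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert r.cohen_d == pytest.approx(d.mean() / d.std(ddof=1))

    def test_identical_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_contrast([1.0, 2.0], [1.0, 2.0])

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=21), rng.normal(size=21)
        r1, r2 = paired_contrast(x, y), paired_contrast(y, x)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.cohen_d == pytest.approx(-r2.cohen_d)
        assert r1.p == pytest.approx(r2.p)

    def test_cohen_d_consistent_with_t(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=21), rng.normal(size=21)
        r = paired_contrast(x, y)
        assert r.cohen_d == pytest.approx(r.t / np.sqrt(21))

    def test_type_one_error_calibrated(self):
        # null differences, n=21, 2000 reps: rejection rate 0.05 ± 0.01,
        # i.e. between 80 and 120 rejections (integer band, inclusive)
        rng = np.random.default_rng(12345)
        rejections = 0
        for _ in range(2000):
            d = rng.normal(size=21)
            r = paired_contrast(d, np.zeros(21))
            rejections += r.p < 0.05
        assert 80 <= rejections <= 120


class TestBhAdjust:
    def test_monotone_and_contractive_on_reapplication(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=12)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # step-up adjustment is not idempotent; reapplying can only
        # increase values further (up to the cap at 1)
        again = bh_adjust(adj)
        assert np.all(again >= adj - 1e-15)
        assert np.all(again <= 1.0)

    def test_equal_p_values_unchanged(self):
        p = np.full(4, 0.03)
        assert np.allclose(bh_adjust(p), p)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_step_up_properties_hold_for_arbitrary_inputs(self, p):
        from statsmodels.stats.multitest import multipletests

        adj = bh_adjust(p)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.allclose(adj, multipletests(p, method="fdr_bh")[1])


class TestMixedModel:
    def _simulate(self, seed, n_groups=21, per=3, b_slope=-5.7, var_u=2.0,
                  var_e=2.9):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), per)
        x = rng.normal(size=n_groups * per)
        u = rng.normal(scale=np.sqrt(var_u), size=n_groups)
        y = 1.0 + b_slope * x + u[g] + rng.normal(scale=np.sqrt(var_e),
                                                  size=n_groups * per)
        return y, x, g

    def test_matches_statsmodels_ml(self):
        import statsmodels.formula.api as smf

        y, x, g = self._simulate(0)
        fit = fit_random_intercept_lmm(y, {"x": x}, g)
        ref = smf.mixedlm("y ~ x", pd.DataFrame({"y": y, "x": x, "g": g}),
                          groups="g").fit(reml=False)
        assert fit.beta == pytest.approx(ref.params.values[:2], rel=1e-4)
        assert fit.var_intercept == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                  abs=1e-3)
        assert fit.var_residual == pytest.approx(ref.scale, rel=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_ols_limit_when_no_group_structure(self):
        # response built with zero between-group variability and group-free
        # covariate: profiled fit collapses to OLS at the λ=0 boundary
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = 2.0 + 0.5 * x + rng.normal(size=60)
        g = np.tile(np.arange(20), 3)
        fit = fit_random_intercept_lmm(y, {"x": x}, g)
        X = np.column_stack([np.ones(60), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if fit.boundary:
            assert fit.beta == pytest.approx(beta_ols, abs=1e-6)
            assert fit.var_intercept == 0.0
            assert fit.icc == 0.0

    def test_parameter_recovery_within_three_se(self):
        y, x, g = self._simulate(77)
        fit = fit_random_intercept_lmm(y, {"x": x}, g)
        slope = fit.coef("x")
        assert abs(slope["b"] - (-5.7)) < 3 * slope["se"]
        assert slope["ci_low"] < -5.7 < slope["ci_high"] or \
            abs(slope["b"] + 5.7) < 3 * slope["se"]

    def test_loglik_is_local_optimum(self):
        y, x, g = self._simulate(5)
        fit = fit_random_intercept_lmm(y, {"x": x}, g)
        from fracatten.stats import _profiled_deviance

        X = np.column_stack([np.ones(len(y)), x])
        slices = [np.where(g == i)[0] for i in np.unique(g)]
        lam = fit.meta["lambda"]
        rng = np.random.default_rng(0)
        for _ in range(100):
            pert = lam * np.exp(rng.normal(scale=0.5)) + 1e-6
            assert _profiled_deviance(pert, X, y, slices)[0] >= -2 * fit.loglik - 1e-9

    def test_bic_counts_all_parameters(self):
        y, x, g = self._simulate(2)
        fit = fit_random_intercept_lmm(y, {"x": x}, g)
        # 2 fixed + 2 variance parameters on 63 observations
        assert fit.bic == pytest.approx(-2 * fit.loglik + 4 * np.log(63))


class TestIccAndBayesFactor:
    def test_icc_examples(self):
        assert icc(0.0, 1.3) == 0.0
        assert icc(0.7, 0.7) == 0.5
        assert icc(2.01, 2.89) == pytest.approx(0.410, abs=5e-4)

    def test_icc_both_zero_rejected(self):
        with pytest.raises(ValueError):
            icc(0.0, 0.0)

    def test_bayes_factor_closed_forms(self):
        assert bic_bayes_factor(290.99, 290.89) == pytest.approx(
            np.exp(0.05), rel=1e-12)
        assert bic_bayes_factor(100.0, 100.0) == 1.0
        assert bic_bayes_factor(102.0, 100.0) == pytest.approx(np.e)
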