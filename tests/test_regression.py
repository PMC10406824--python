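import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmontanum import regression as reg


def _xy(rng, n=100, slope=2.0, noise=1.0):
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = slope * x1 + rng.normal(scale=noise, size=n)
    return pd.Series(y, name="y"), pd.DataFrame({"x1": x1, "x2": x2})


class TestFitOls:
    def test_study_heterozygosity_on_log_size(self, fixtures):
        t3 = fixtures.table3
        fit = reg.fit_ols(t3["H_o"], t3[["N"]], log_terms=("N",), response="H_o")
        assert fit.r2 == pytest.approx(0.67, abs=0.02)

    def test_perfect_fit(self):
        x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        fit = reg.fit_ols(pd.Series([1.0, 2.0, 3.0, 4.0]), x)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_point_slope_closed_form(self):
        x = pd.DataFrame({"x": [1.0, 3.0, 1.0]})
        y = pd.Series([2.0, 8.0, 2.0])
        fit = reg.fit_ols(y, x, standardize=False)
        assert fit.coef["x"] == pytest.approx(6.0 / 2.0)

    def test_standardized_coefficients_unit_invariant(self, rng):
        y, X = _xy(rng)
        a = reg.fit_ols(y, X)
        b = reg.fit_ols(y, X.assign(x1=X.x1 * 1000.0))
        assert a.coef["x1"] == pytest.approx(b.coef["x1"])
        assert a.r2 == pytest.approx(b.r2)
        # raw coefficients back-transform correctly
        assert b.coef_raw["x1"] == pytest.approx(a.coef_raw["x1"] / 1000.0)

    def test_constant_predictor_rejected(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(reg.SingularityError, match="constant"):
            reg.fit_ols(pd.Series([1.0, 2.0, 3.0, 4.0]), X)

    def test_collinear_terms_named(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.raises(reg.SingularityError, match="a.*b"):
            reg.fit_ols(pd.Series(rng.normal(size=30)), X)


class TestBackwardSelect:
    def test_significant_model_returned_unchanged(self, rng):
        y, X = _xy(rng, slope=3.0, noise=0.5)
        X = X[["x1"]]
        fit, trace = reg.backward_select(y, X)
        assert trace == []
        assert fit.terms == ["x1"]

    def test_noise_term_dropped_signal_kept(self, rng):
        y, X = _xy(rng, n=100, slope=2.0)
        fit, trace = reg.backward_select(y, X, alpha=0.1)
        assert fit.terms == ["x1"]
        assert [s.dropped for s in trace] == ["x2"]
        assert trace[0].p_at_drop > 0.1
        assert np.isfinite(trace[0].anova_p)

    def test_intercept_only_rate_matches_per_step_type_one_error(self):
        """Pure-noise responses reach the intercept-only model at roughly the
        rate implied by the alpha=0.1 screening: the final model is non-empty
        about as often as the smallest of three null p-values falls below
        0.1 (1 - 0.9^3 = 0.27 for independent predictors)."""
        rng = np.random.default_rng(5)
        kept = 0
        n_rep = 200
        for _ in range(n_rep):
            X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
            y = pd.Series(rng.normal(size=60))
            fit, _ = reg.backward_select(y, X, alpha=0.1)
            kept += bool(fit.terms)
        assert 0.15 <= kept / n_rep <= 0.40

    def test_aic_only_rises_near_its_theoretical_boundary(self, rng):
        """Dropping one term changes AIC by n ln(1 + t^2/df) - 2, which is
        negative whenever t^2 < df (e^{2/n} - 1) ~ 2, i.e. for any drop with
        p well above ~0.17.  AIC increases can therefore only occur in the
        narrow band alpha < p < ~0.2, and most drops must lower AIC."""
        rises = total = 0
        for rep in range(40):
            r = np.random.default_rng(rep)
            X = pd.DataFrame(r.normal(size=(100, 4)), columns=list("abcd"))
            y = pd.Series(2 * X["a"].values + r.normal(size=100))
            _, trace = reg.backward_select(y, X)
            for step in trace:
                total += 1
                if step.aic_after > step.aic_before + 1e-9:
                    rises += 1
                    assert step.p_at_drop < 0.2
        assert total > 0
        assert rises / total < 0.5


class TestContributionShares:
    def test_single_predictor_is_everything(self, rng):
        y, X = _xy(rng)
        shares = reg.contribution_shares(reg.fit_ols(y, X[["x1"]]))
        assert shares["x1"] == pytest.approx(100.0)

    def test_ratio_of_standardized_magnitudes(self):
        fit = reg.FitResult(
            response="y", terms=["a", "b"],
            coef=pd.Series({"const": 0.0, "a": 1.0, "b": -3.0}),
            coef_raw=pd.Series(), se=pd.Series(), pvalues=pd.Series(),
            r2=0.5, r2_adj=0.4, aic=0.0, n=10, resid=np.zeros(10),
            standardized=True)
        shares = reg.contribution_shares(fit)
        assert shares["a"] == pytest.approx(25.0)
        assert shares["b"] == pytest.approx(75.0)

    def test_shares_sum_to_hundred(self, rng):
        y, X = _xy(rng)
        shares = reg.contribution_shares(reg.fit_ols(y, X))
        assert shares.sum() == pytest.approx(100.0)


class TestCorrelation:
    def test_study_he_i_association(self, fixtures):
        t3 = fixtures.table3
        res = reg.correlation(t3["H_e"], t3["I"])
        assert res.coefficient == pytest.approx(0.90, abs=0.02)

    def test_self_correlation(self):
        x = pd.Series([1.0, 2.0, 5.0, 3.0])
        assert reg.correlation(x, x).coefficient == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert reg.correlation(x, y).coefficient == pytest.approx(
            reg.correlation(y, x).coefficient)

    def test_permutation_p_uniform_under_null(self):
        """Sampled permutation p-values are roughly uniform for independent
        Gaussians (calibration at n=30, 199 permutations)."""
        rng = np.random.default_rng(8)
        ps = []
        for k in range(200):
            x, y = rng.normal(size=30), rng.normal(size=30)
            ps.append(reg.correlation(x, y, n_perm=199, seed=k).p_permutation)
        ps = np.array(ps)
        # add-one correction keeps p in [1/200, 1]
        assert ps.min() >= 1 / 200
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            reg.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupDifference:
    def test_no_between_group_variance(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        out = reg.group_difference(vals, groups, posthoc=False)
        assert out.statistic == pytest.approx(0.0)

    def test_anova_matches_hand_computation(self):
        """Textbook 3-group one-way ANOVA against the explicit SS decomposition."""
        g = {"a": [6.0, 8.0, 4.0, 5.0], "b": [8.0, 12.0, 9.0, 11.0],
             "c": [13.0, 9.0, 11.0, 8.0]}
        vals = sum(g.values(), [])
        groups = [k for k in g for _ in g[k]]
        grand = np.mean(vals)
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in g.values())
        ss_within = sum((x - np.mean(v)) ** 2 for v in g.values() for x in v)
        f_hand = (ss_between / 2) / (ss_within / 9)
        out = reg.group_difference(vals, groups)
        assert out.statistic == pytest.approx(f_hand)
        assert not out.posthoc.empty

    def test_kruskal_detects_rank_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(1.5, 1.0, 20)
        out = reg.group_difference(
            np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20,
            parametric=False)
        assert out.test == "kruskal"
        assert out.pvalue < 0.01
        assert "p_holm" in out.posthoc.columns

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            reg.group_difference([1.0, 2.0], ["a", "a"])
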