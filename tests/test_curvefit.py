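import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import TRUTHS
from marshphen import curvefit as cf
from marshphen.timeseries import ViSeries


class TestEvalModel:
    def test_ag_branch_continuity_at_peak(self):
        """Both AG branches give exp(0) = 1 at t = a1, so f(a1) = c1 + c2."""
        coefs = TRUTHS["AG"]
        assert cf.eval_model("AG", coefs, coefs["a1"]) == pytest.approx(
            coefs["c1"] + coefs["c2"], abs=1e-14)

    @given(a1=st.floats(50, 300), a2=st.floats(5, 100), a3=st.floats(5, 100),
           a4=st.floats(1.0, 8.0))
    def test_ag_branches_agree_at_a1(self, a1, a2, a3, a4):
        c = {"c1": 0.1, "c2": 0.5, "a1": a1, "a2": a2, "a3": a3, "a4": a4}
        eps = 1e-7
        left = cf.eval_model("AG", c, a1 - eps)
        right = cf.eval_model("AG", c, a1 + eps)
        assert left == pytest.approx(right, abs=1e-6)

    def test_tf_reduces_to_constant(self):
        c = {"c": 0.37, "w": cf.W_ANNUAL, "a1": 0, "b1": 0, "a2": 0, "b2": 0}
        t = np.linspace(1, 365, 50)
        assert np.allclose(cf.eval_model("TF", c, t), 0.37)

    def test_dl_scalar_oracle(self):
        """Hand-evaluated double logistic at t = 100."""
        c = {"c1": 0.1, "c2": 0.5, "a1": 100, "a2": 5, "a3": 250, "a4": 5}
        expected = 0.1 + 0.5 * (0.5 - 1.0 / (1.0 + np.exp(30.0)))
        assert cf.eval_model("DL", c, 100) == pytest.approx(expected, abs=1e-12)
        assert cf.eval_model("DL", c, 100) == pytest.approx(0.35, abs=1e-6)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            cf.eval_model("AG", {"c1": 0, "c2": 1, "a1": 100, "a2": -1,
                                 "a3": 10, "a4": 2}, 50)


class TestJacobian:
    @pytest.mark.parametrize("method", cf.METHODS)
    def test_matches_finite_differences(self, method, irregular_days):
        c = np.array(list(TRUTHS[method].values()))
        J = cf.model_jacobian(method, c, irregular_days)
        for k in range(6):
            h = 1e-6 * max(abs(c[k]), 1e-3)
            cp, cm = c.copy(), c.copy()
            cp[k] += h
            cm[k] -= h
            num = (cf.eval_model(method, cp, irregular_days)
                   - cf.eval_model(method, cm, irregular_days)) / (2 * h)
            assert np.abs(J[:, k] - num).max() < 1e-6


class TestFitCurve:
    @pytest.mark.parametrize("method", cf.METHODS)
    def test_noise_free_recovery(self, method, make_series):
        """Matching-family refit of a clean 40-point series recovers all six
        coefficients to 1e-4 relative with essentially perfect R^2."""
        series = make_series(method)
        fit = cf.fit_curve(series, method)
        truth = np.array(list(TRUTHS[method].values()))
        assert fit.converged
        assert np.abs((fit.coef_array - truth) / truth).max() < 1e-4
        assert fit.r2 > 0.9999

    def test_tf_frequency_recovered(self, make_series):
        fit = cf.fit_curve(make_series("TF"), "TF")
        w_true = TRUTHS["TF"]["w"]
        assert abs(fit.coefficients["w"] - w_true) / w_true < 1e-3

    def test_constant_series_degenerate(self, irregular_days):
        series = ViSeries("p", irregular_days, np.full(40, 0.4), "NDVI")
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = cf.fit_curve(series, "DL")
        assert fit.coefficients["c2"] < 0.01  # amplitude ~ 0
        assert fit.r2 == 0.0

    def test_short_series_precondition(self):
        series = ViSeries("p", np.arange(5.0) + 1, np.full(5, 0.4), "NDVI")
        with pytest.raises(ValueError, match="fallback"):
            cf.fit_curve(series, "DL")

    def test_objective_not_worse_than_start(self, make_series):
        """The optimizer's final SSE never exceeds the initial guess's."""
        series = make_series("DL", noise_sigma=0.05, seed=3)
        x0 = cf._initial_guess("DL", series.days, series.values)
        sse0 = np.sum((cf.eval_model("DL", x0, series.days) - series.values) ** 2)
        fit = cf.fit_curve(series, "DL")
        sse = np.sum((fit(series.days) - series.values) ** 2)
        assert sse <= sse0 + 1e-12

    def test_cross_family_sanity(self, make_series):
        """On clean DL truth the DL fit is at least as good as AG and TF."""
        series = make_series("DL")
        r2 = {m: cf.fit_curve(series, m).r2 for m in cf.METHODS}
        assert r2["DL"] >= r2["AG"] - 1e-12
        assert r2["DL"] >= r2["TF"] - 1e-12

    def test_frozen_w_matches_harmonic_oracle(self, make_series):
        """Nonlinear TF optimisation with w pinned equals the closed-form
        harmonic linear least-squares solution."""
        series = make_series("TF", noise_sigma=0.03, seed=11)
        fit = cf.fit_curve(series, "TF", freeze_w=True)
        beta = cf.harmonic_least_squares(series.days, series.values)
        for k in cf.COEF_NAMES["TF"]:
            assert fit.coefficients[k] == pytest.approx(beta[k], abs=1e-8)


class TestRSquared:
    def test_perfect_fit(self, make_series):
        series = make_series("DL")
        fit = cf.FittedCurve("DL", TRUTHS["DL"], np.nan, 40, True)
        assert cf.r_squared(series, fit) == pytest.approx(1.0, abs=1e-12)

    def test_mean_predictor_scores_zero(self, irregular_days):
        rng = np.random.default_rng(0)
        values = rng.normal(0.5, 0.1, 40)
        series = ViSeries("p", irregular_days, values, "NDVI")
        mean_fit = lambda t: np.full(np.shape(t), values.mean())
        assert cf.r_squared(series, mean_fit) == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_mean_goes_negative(self, irregular_days):
        values = np.full(40, 0.5) + np.linspace(-0.01, 0.01, 40)
        series = ViSeries("p", irregular_days, values, "NDVI")
        bad_fit = lambda t: np.full(np.shape(t), 2.0)
        assert cf.r_squared(series, bad_fit) < 0


class TestCompareFitAccuracy:
    def test_identical_groups(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0.8, 0.05, 30)
        res = cf.compare_fit_accuracy({"a": g, "b": g.copy()})
        assert res.table["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.table["p"].iloc[0] > 0.9

    def test_separated_groups_significant(self):
        """Large offset, tiny variance: p below 1e-6, checked against a
        direct studentized-range computation."""
        from scipy.stats import studentized_range
        rng = np.random.default_rng(2)
        a = rng.normal(0.2, 0.001, 20)
        b = rng.normal(0.9, 0.001, 20)
        res = cf.compare_fit_accuracy({"a": a, "b": b})
        assert res.table["p"].iloc[0] < 1e-6
        # oracle: q statistic for the two-group case
        n = 20
        mse = (a.var(ddof=1) + b.var(ddof=1)) / 2
        q = abs(b.mean() - a.mean()) / np.sqrt(mse / n)
        p_oracle = studentized_range.sf(q, 2, 2 * n - 2)
        assert res.table["p"].iloc[0] == pytest.approx(p_oracle, rel=0.2, abs=1e-9)

    def test_output_column_layout(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(m, 0.05, 10)
                  for k, m in (("NDVI", 0.7), ("SAVI", 0.72), ("EVI", 0.8))}
        res = cf.compare_fit_accuracy(groups)
        assert list(res.table.columns) == ["class1", "class2", "lower",
                                           "estimate", "upper", "p"]
        assert len(res.table) == 3  # all unordered pairs
        assert ((res.table["lower"] <= res.table["estimate"])
                & (res.table["estimate"] <= res.table["upper"])).all()
        assert res.table["p"].between(0, 1).all()
        assert 0 <= res.anova_p <= 1

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cf.compare_fit_accuracy({"a": [0.5, 0.5], "b": [0.7, 0.7]})
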