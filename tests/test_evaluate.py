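"""GLM validation machinery: scaling, fits, selection, dispersion, R2,
multiple-test summary, leverage."""

import itertools

import numpy as np
import pandas as pd
import pytest

from parweb.evaluate import (
    ModelSpec,
    _valid_subsets,
    all_subsets_selection,
    bernoulli_multiple_tests,
    fit_glm,
    leverage_outliers,
    nakagawa_r2,
    overdispersion_check,
    scale_center,
)


class TestScaleCenter:
    def test_hand_worked_example(self):
        assert np.allclose(scale_center([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_on_standardised_data(self):
        x = scale_center(np.random.default_rng(0).normal(size=50))
        assert np.allclose(scale_center(x), x, atol=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            scale_center([5, 5, 5])


class TestBernoulliMultipleTests:
    def test_worked_values(self):
        assert bernoulli_multiple_tests(6, 3, 0.05) == pytest.approx(0.0022299, abs=1e-6)
        assert bernoulli_multiple_tests(2, 2, 0.05) == pytest.approx(0.0025)
        assert bernoulli_multiple_tests(6, 0, 0.05) == 1.0

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2, 0.5])
    def test_matches_exhaustive_enumeration(self, alpha):
        """Brute force over all 2^N significance outcomes."""
        for n in range(1, 11):
            for k in range(n + 1):
                total = 0.0
                for outcome in itertools.product([0, 1], repeat=n):
                    hits = sum(outcome)
                    if hits >= k:
                        total += alpha**hits * (1 - alpha) ** (n - hits)
                assert bernoulli_multiple_tests(n, k, alpha) == pytest.approx(
                    total, abs=1e-12
                )

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bernoulli_multiple_tests(3, 4, 0.05)
        with pytest.raises(ValueError):
            bernoulli_multiple_tests(3, 1, 1.5)


def poisson_data(n=500, slope=0.5, intercept=0.2, seed=0):
    rng = np.random.default_rng(seed)
    x = scale_center(rng.normal(size=n))
    y = rng.poisson(np.exp(intercept + slope * x))
    return pd.DataFrame({"x": x, "y": y})


class TestFitGlm:
    def test_poisson_slope_recovery(self):
        data = poisson_data()
        spec = ModelSpec(family="poisson", response="y", terms=("x",))
        fit = fit_glm(spec, data)
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(0.5, abs=0.15)
        assert fit.converged

    def test_intercept_only_poisson_closed_form(self):
        data = poisson_data()
        spec = ModelSpec(family="poisson", response="y")
        fit = fit_glm(spec, data)
        assert fit.coefficients.loc["Intercept", "estimate"] == pytest.approx(
            np.log(data["y"].mean()), abs=1e-8
        )

    def test_binomial_aggregated_equals_expanded(self):
        rng = np.random.default_rng(3)
        agg = pd.DataFrame({
            "x": scale_center(rng.normal(size=40)),
            "trials": rng.integers(2, 20, 40),
        })
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * agg["x"])))
        agg["events"] = rng.binomial(agg["trials"], p)
        expanded = agg.loc[agg.index.repeat(agg["trials"])].copy()
        expanded["hit"] = [
            1 if i < e else 0
            for e, t in zip(agg["events"], agg["trials"])
            for i in range(t)
        ]
        fit_a = fit_glm(
            ModelSpec(family="binomial", response=("events", "trials"), terms=("x",)),
            agg,
        )
        fit_b = fit_glm(
            ModelSpec(family="binomial", response="hit", terms=("x",)), expanded
        )
        assert np.allclose(
            fit_a.coefficients["estimate"], fit_b.coefficients["estimate"], atol=1e-8
        )

    def test_aicc_exceeds_aic(self):
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)),
                      poisson_data(n=30))
        assert fit.aicc > fit.aic

    def test_aic_invariant_to_affine_predictor_rescaling(self):
        data = poisson_data()
        data["x2"] = 10 * data["x"] + 3
        a = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)), data)
        b = fit_glm(ModelSpec(family="poisson", response="y", terms=("x2",)), data)
        assert a.aic == pytest.approx(b.aic, abs=1e-6)

    def test_degenerate_response_errors(self):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2, 2, 2]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)), data)


class TestAllSubsets:
    def test_marginality_never_violated(self):
        terms = ("a", "b", "a:b", "c")
        for subset in _valid_subsets(terms):
            if "a:b" in subset:
                assert "a" in subset and "b" in subset

    def test_strong_predictor_retained(self):
        data = poisson_data(n=500, slope=0.8, seed=1)
        data["noise"] = scale_center(np.random.default_rng(2).normal(size=500))
        spec = ModelSpec(family="poisson", response="y", terms=("x", "noise"))
        result = all_subsets_selection(spec, data)
        assert "x" in result.best_terms

    def test_pure_noise_predictor_dropped(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame({
            "y": rng.poisson(2.0, 500),
            "noise": scale_center(rng.normal(size=500)),
        })
        spec = ModelSpec(family="poisson", response="y", terms=("noise",))
        result = all_subsets_selection(spec, data)
        assert result.best_terms == ()

    def test_inclusion_fractions_within_unit_interval(self):
        data = poisson_data(n=200, seed=5)
        spec = ModelSpec(family="poisson", response="y", terms=("x",))
        result = all_subsets_selection(spec, data)
        assert ((result.inclusion_fractions >= 0) & (result.inclusion_fractions <= 1)).all()


class TestOverdispersion:
    def test_equidispersed_poisson_ratio_near_one(self):
        data = poisson_data(n=2000, seed=10)
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)), data)
        ratio, p, flag = overdispersion_check(fit)
        assert 0.8 <= ratio <= 1.2
        assert not flag

    def test_negative_binomial_flags(self):
        rng = np.random.default_rng(20)
        x = scale_center(rng.normal(size=800))
        mu = np.exp(1.0 + 0.3 * x)
        y = rng.negative_binomial(n=1.0, p=1.0 / (1.0 + mu))
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)), data)
        ratio, p, flag = overdispersion_check(fit)
        assert ratio > 2 and flag


class TestNakagawaR2:
    def test_no_grouping_marginal_equals_conditional(self):
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)),
                      poisson_data())
        m, c = nakagawa_r2(fit)
        assert m == pytest.approx(c)

    def test_intercept_only_marginal_zero(self):
        fit = fit_glm(ModelSpec(family="poisson", response="y"), poisson_data())
        m, _ = nakagawa_r2(fit)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_identity_matches_classical_r2(self):
        rng = np.random.default_rng(8)
        x = scale_center(rng.normal(size=300))
        y = 2.0 + 1.5 * x + rng.normal(0, 1.0, 300)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_glm(ModelSpec(family="gaussian", response="y", terms=("x",)), data)
        m, c = nakagawa_r2(fit)
        yhat = fit._sm_result.mu
        classical = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert m == pytest.approx(classical, abs=1e-6)
        assert m == pytest.approx(c)

    def test_bounds_and_ordering(self):
        rng = np.random.default_rng(30)
        data = poisson_data(n=300, seed=30)
        data["g"] = rng.integers(0, 6, len(data)).astype(str)
        fit = fit_glm(
            ModelSpec(family="poisson", response="y", terms=("x",), groups="g"),
            data,
        )
        m, c = nakagawa_r2(fit)
        assert 0 <= m <= c <= 1


class TestLeverage:
    def test_hat_values_sum_to_parameter_count(self):
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)),
                      poisson_data(n=100))
        report = leverage_outliers(fit)
        assert report["hat"].sum() == pytest.approx(2.0, abs=1e-8)
        assert ((report["hat"] >= 0) & (report["hat"] <= 1)).all()

    def test_extreme_point_flagged(self):
        rng = np.random.default_rng(1)
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0] * 4)
        y = rng.poisson(np.exp(0.5 + 0.01 * x))
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_glm(ModelSpec(family="poisson", response="y", terms=("x",)), data)
        report = leverage_outliers(fit)
        flagged_x = data.loc[report["flagged"], "x"]
        assert (flagged_x == 100.0).all() and len(flagged_x) > 0

    def test_uniform_design_has_no_flags(self):
        data = poisson_data(n=50)
        fit = fit_glm(ModelSpec(family="poisson", response="y"), data)
        report = leverage_outliers(fit)
        # intercept-only: every hat value is exactly 1/n < 2p/n
        assert not report["flagged"].any()
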