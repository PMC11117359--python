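"""All-subsets Gaussian GLMs, AICc ranking, weights, model averaging."""

import math

import numpy as np
import pandas as pd
import pytest

from camtrapniche.habitat import (
    ModelFitRecord,
    adjusted_r2,
    aicc,
    best_model_set,
    fit_all_subsets,
    gaussian_loglik,
    mmi_summary,
    rank_and_weight,
    screen_collinearity,
)


def _record(preds, aicc_value, coefs=None, ses=None):
    coefs = coefs or {}
    ses = ses or {}
    return ModelFitRecord(
        predictors=tuple(preds), coefficients=coefs, std_errors=ses,
        loglik=0.0, k=len(preds) + 2, n=26, r2=0.0, adj_r2=0.0, aicc=aicc_value,
    )


class TestScreening:
    def test_identical_columns_one_dropped(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        res = screen_collinearity(df)
        assert len(res.retained) == 2
        assert "c" in res.retained

    def test_uncorrelated_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        res = screen_collinearity(df)
        assert sorted(res.retained) == list("abcd")

    def test_drop_preference_breaks_tie(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({
            "keepme": x + rng.normal(scale=0.05, size=40),
            "dropme": x + rng.normal(scale=0.05, size=40),
            "other": rng.normal(size=40),
        })
        res = screen_collinearity(df, drop_preference=["dropme"])
        assert "dropme" not in res.retained
        assert "keepme" in res.retained

    def test_constant_predictor_flagged(self, rng):
        df = pd.DataFrame({"flat": np.ones(20), "x": rng.normal(size=20)})
        res = screen_collinearity(df)
        assert "flat" not in res.retained
        assert res.dropped[0][0] == "flat"


class TestFitAllSubsets:
    def test_subset_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = rng.normal(size=20)
        assert len(fit_all_subsets(y, X)) == 4

    def test_single_predictor_matches_closed_form(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 3.0 * x + rng.normal(scale=0.5, size=30)
        X = pd.DataFrame({"x": x})
        models = fit_all_subsets(y, X)
        m = next(m for m in models if m.predictors == ("x",))
        sxy = np.cov(x, y, ddof=1)[0, 1]
        slope = sxy / np.var(x, ddof=1)
        assert m.coefficients["x"] == pytest.approx(slope, rel=1e-10)

    def test_intercept_only_loglik_closed_form(self, rng):
        y = rng.normal(size=25)
        models = fit_all_subsets(y, pd.DataFrame(index=range(25)))
        m = models[0]
        n = len(y)
        sigma2 = np.mean((y - y.mean()) ** 2)
        expected = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        assert m.loglik == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_lstsq_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(26, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=26)
        for m in fit_all_subsets(y, X):
            design = np.column_stack(
                [np.ones(26)] + [X[p].to_numpy() for p in m.predictors]
            )
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            got = [m.coefficients["(Intercept)"]] + [m.coefficients[p] for p in m.predictors]
            np.testing.assert_allclose(got, beta, atol=1e-8)


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(0.0, 2, 26) == pytest.approx(4 + 12 / 23)

    def test_converges_to_aic(self):
        k, ll = 3, -10.0
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, 10**6) - aic) < 1e-4

    def test_penalty_monotone_in_k(self):
        assert aicc(-5.0, 2, 26) < aicc(-5.0, 4, 26)

    def test_small_n_infinite(self):
        assert aicc(0.0, 10, 11) == math.inf


class TestRankAndWeight:
    def test_single_model(self):
        out = rank_and_weight([_record(["a"], 100.0)])
        assert out[0].weight == pytest.approx(1.0)
        assert out[0].delta_aicc == 0.0

    def test_delta_two_weight_ratio(self):
        out = rank_and_weight([_record(["a"], 100.0), _record(["b"], 102.0)])
        assert out[1].weight / out[0].weight == pytest.approx(math.exp(-1.0))

    def test_equal_aicc_equal_weights(self):
        out = rank_and_weight([_record([p], 50.0) for p in "abcd"])
        for m in out:
            assert m.weight == pytest.approx(0.25)

    def test_weights_sum_to_one(self, rng):
        out = rank_and_weight([_record([p], 100 + 10 * rng.random()) for p in "abcdefg"])
        assert sum(m.weight for m in out) == pytest.approx(1.0, abs=1e-12)

    def test_best_set_threshold(self):
        out = rank_and_weight(
            [_record(["a"], 100.0), _record(["b"], 101.9), _record(["c"], 102.1)]
        )
        assert {m.predictors for m in best_model_set(out)} == {("a",), ("b",)}

    def test_invariant_to_loglik_shift(self, rng):
        models = [
            ModelFitRecord((p,), {}, {}, ll, 3, 26, 0, 0, aicc=aicc(ll, 3, 26))
            for p, ll in zip("abcd", rng.normal(size=4))
        ]
        best1 = rank_and_weight(list(models))[0].predictors
        shifted = [
            ModelFitRecord(m.predictors, {}, {}, m.loglik + 7, 3, 26, 0, 0,
                           aicc=aicc(m.loglik + 7, 3, 26))
            for m in models
        ]
        assert rank_and_weight(shifted)[0].predictors == best1


class TestMmiSummary:
    def test_predictor_in_every_model(self):
        models = rank_and_weight([
            _record(["a"], 100.0, {"a": 1.0}, {"a": 0.1}),
            _record(["a", "b"], 101.0, {"a": 1.2, "b": 0.5}, {"a": 0.1, "b": 0.2}),
        ])
        s = mmi_summary(models)
        assert s.selection_probability["a"] == pytest.approx(1.0)

    def test_conditional_weighted_mean(self):
        m1 = _record(["x"], 0.0, {"x": 1.0}, {"x": 0.0})
        m2 = _record(["x"], 0.0, {"x": 2.0}, {"x": 0.0})
        m1.weight, m2.weight = 0.6, 0.4
        m1.delta_aicc = m2.delta_aicc = 0.0
        s = mmi_summary([m1, m2])
        assert s.coefficient["x"] == pytest.approx(1.4)

    def test_predictor_in_one_model(self):
        m1 = _record(["x"], 0.0, {"x": 5.0}, {"x": 0.3})
        m2 = _record([], 0.0)
        m1.weight, m2.weight = 0.3, 0.7
        s = mmi_summary([m1, m2])
        assert s.selection_probability["x"] == pytest.approx(0.3)
        assert s.coefficient["x"] == pytest.approx(5.0)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 26, 3) == pytest.approx(1.0)

    def test_intercept_only(self):
        assert adjusted_r2(0.0, 26, 0) == pytest.approx(0.0)

    def test_three_point_hand_computation(self):
        # y = (0, 1, 3) on x = (0, 1, 2): R2 = 1 - SSE/SST
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 3.0])
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        icept = y.mean() - slope * x.mean()
        sse = np.sum((y - icept - slope * x) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1 - sse / sst
        assert adjusted_r2(r2, 3, 1) == pytest.approx(1 - (1 - r2) * 2 / 1)


class TestParameterRecovery:
    def test_true_predictors_have_top_selection_probabilities(self, rng):
        """2 true of 4 candidates, n=26, moderate noise: top-2 in >=80% of runs."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            X = pd.DataFrame(rng.normal(size=(26, 4)), columns=["t1", "t2", "n1", "n2"])
            y = 1.0 * X["t1"] - 1.0 * X["t2"] + rng.normal(scale=1.0, size=26)
            models = rank_and_weight(fit_all_subsets(y.to_numpy(), X))
            s = mmi_summary(models)
            top2 = sorted(s.selection_probability,
                          key=s.selection_probability.get, reverse=True)[:2]
            hits += set(top2) == {"t1", "t2"}
        assert hits / n_rep >= 0.8

    def test_averaged_coefficients_near_truth(self, rng):
        errors = []
        for _ in range(30):
            X = pd.DataFrame(rng.normal(size=(26, 4)), columns=["t1", "t2", "n1", "n2"])
            y = 1.0 * X["t1"] - 1.0 * X["t2"] + rng.normal(scale=1.0, size=26)
            s = mmi_summary(rank_and_weight(fit_all_subsets(y.to_numpy(), X)))
            errors.append(abs(s.coefficient["t1"] - 1.0) / s.std_error["t1"])
        assert np.mean(errors) < 2.0
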