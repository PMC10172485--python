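"""Change-ratio outcome, feature construction, collinearity, OLS, LOOCV."""

from __future__ import annotations

import numpy as np
import pytest

from cohnet.graph import NetworkMetrics
from cohnet.prediction import (
    backward_eliminate,
    build_features,
    collinearity_diagnostics,
    evaluate_prediction,
    fit_linear,
    loocv,
    panss_change_ratio,
)


def metrics(clu=0.5, le=0.5, ge=0.5, path_length=2.0) -> NetworkMetrics:
    return NetworkMetrics(clu=clu, le=le, ge=ge, path_length=path_length,
                          d=np.zeros((2, 2)))


class TestChangeRatio:
    def test_no_change_is_zero(self):
        assert panss_change_ratio(80, 80) == 0.0

    def test_group_mean_scores_give_023(self):
        # improvement from a 74.62 group mean to 57.24
        assert panss_change_ratio(74.62, 57.24) == pytest.approx(0.2329, abs=5e-4)

    def test_worsening_gives_negative_ratio(self):
        assert panss_change_ratio(60, 75) < 0

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            panss_change_ratio(0, 40)

    def test_below_scale_minimum_warns(self):
        with pytest.warns(UserWarning, match="minimum"):
            panss_change_ratio(40, 25)


class TestBuildFeatures:
    TASKS = ("THT", "TMT-A", "TMT-B")

    def test_identical_phases_give_zero_features(self):
        before = {"s1": {t: metrics() for t in self.TASKS}}
        after = {"s1": {t: metrics() for t in self.TASKS}}
        table = build_features(before, after)
        assert np.allclose(table.to_numpy(), 0.0)
        assert list(table.columns) == ["delta_clu", "delta_le", "delta_ge", "delta_l"]

    def test_single_task_delta_passthrough(self):
        before = {"s1": {"THT": metrics(path_length=2.0)}}
        after = {"s1": {"THT": metrics(path_length=1.8)}}
        table = build_features(before, after)
        assert table.loc["s1", "delta_l"] == pytest.approx(-0.2)

    def test_mean_over_tasks(self):
        before = {"s1": {t: metrics(ge=0.5) for t in self.TASKS}}
        after = {"s1": {
            "THT": metrics(ge=0.6), "TMT-A": metrics(ge=0.7), "TMT-B": metrics(ge=0.5)
        }}
        table = build_features(before, after)
        assert table.loc["s1", "delta_ge"] == pytest.approx(0.1)

    def test_per_task_mode_keeps_twelve_features(self):
        before = {f"s{i}": {t: metrics() for t in self.TASKS} for i in range(20)}
        after = {f"s{i}": {t: metrics() for t in self.TASKS} for i in range(20)}
        with pytest.warns(UserWarning, match="unstable"):
            table = build_features(before, after, aggregation="per_task")
        assert table.shape == (20, 12)

    def test_missing_phase_rejected(self):
        before = {"s1": {t: metrics() for t in self.TASKS}}
        with pytest.raises(KeyError, match="s1"):
            build_features(before, {})


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        x = np.array([[1, 0], [-1, 0], [0, 1], [0, -1.0]])
        vif, tol, flags = collinearity_diagnostics(x)
        assert np.allclose(vif, 1.0)
        assert np.allclose(tol, 1.0)
        assert not flags.any()

    def test_duplicated_column_infinite_vif(self, rng):
        c = rng.normal(size=10)
        vif, tol, flags = collinearity_diagnostics(np.column_stack([c, c]))
        assert np.isinf(vif).all()
        assert flags.all()

    def test_correlated_pair_closed_form(self, rng):
        # for two predictors VIF = 1 / (1 - r^2); r = 0.9 -> ~5.26
        n = 100_000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        vif, _, _ = collinearity_diagnostics(np.column_stack([x1, x2]))
        assert vif[0] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(ValueError):
            collinearity_diagnostics(np.zeros((3, 4)))


class TestFitLinear:
    def test_exact_model_recovered(self, rng):
        x = rng.normal(size=(30, 1))
        y = 0.197 - 2.081 * x[:, 0]
        intercept, coefs = fit_linear(x, y)
        assert intercept == pytest.approx(0.197, abs=1e-10)
        assert coefs[0] == pytest.approx(-2.081, abs=1e-10)

    def test_constant_outcome_zero_slope(self, rng):
        x = rng.normal(size=(20, 2))
        intercept, coefs = fit_linear(x, np.full(20, 3.0))
        assert np.allclose(coefs, 0.0, atol=1e-10)
        assert intercept == pytest.approx(3.0)

    def test_unbiased_under_noise(self, rng):
        # 500 sims at n=21: mean slope within 2 SE of truth
        slopes = []
        for _ in range(500):
            x = rng.normal(size=(21, 1))
            y = 1.0 + 2.5 * x[:, 0] + rng.normal(0, 1, 21)
            slopes.append(fit_linear(x, y)[1][0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.5) < 2 * se + 1e-9

    def test_rank_deficiency_rejected(self, rng):
        c = rng.normal(size=12)
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear(np.column_stack([c, 2 * c]), rng.normal(size=12))


class TestEvaluatePrediction:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=10)
        r, p, rmse = evaluate_prediction(y, y)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0)

    def test_constant_offset_keeps_r_one(self, rng):
        y = rng.normal(size=10)
        r, _, rmse = evaluate_prediction(y + 0.3, y)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.3)

    def test_hand_case_n3(self):
        r, _, rmse = evaluate_prediction([0.1, 0.2, 0.3], [0.1, 0.3, 0.2])
        assert r == pytest.approx(0.5)
        assert rmse == pytest.approx(np.sqrt(0.02 / 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_prediction([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestLoocv:
    def test_noiseless_linear_is_exact(self, rng):
        x = rng.normal(size=(21, 4))
        beta = np.array([0.5, -2.0, 1.0, 0.25])
        y = 0.197 + x @ beta
        model = loocv(x, y)
        assert model.r == pytest.approx(1.0)
        assert model.rmse == pytest.approx(0.0, abs=1e-10)
        assert model.rmse_percent == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(model.loocv_predictions, y, atol=1e-8)
        assert model.intercept == pytest.approx(0.197)

    def test_predictions_match_independent_sklearn_route(self, rng):
        # our fold loop against sklearn LeaveOneOut + LinearRegression
        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import LeaveOneOut, cross_val_predict

        x = rng.normal(size=(21, 4))
        y = 0.2 - 1.5 * x[:, 3] + rng.normal(0, 0.3, 21)
        ours = loocv(x, y).loocv_predictions
        ref = cross_val_predict(LinearRegression(), x, y, cv=LeaveOneOut())
        assert np.allclose(ours, ref, atol=1e-10)

    def test_null_features_r_negatively_biased(self, rng):
        # held-out predictions are anticorrelated with held-out values via
        # the training mean: under the null, mean LOOCV r is clearly below
        # zero at small n (exactly -1 for an intercept-only model), and it
        # must agree with the independent sklearn LOOCV route
        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import LeaveOneOut, cross_val_predict

        rs, rs_ref = [], []
        for _ in range(200):
            x = rng.normal(size=(21, 1))
            y = rng.normal(size=21)
            rs.append(loocv(x, y).r)
            ref = cross_val_predict(LinearRegression(), x, y, cv=LeaveOneOut())
            rs_ref.append(np.corrcoef(ref, y)[0, 1])
        assert np.mean(rs) == pytest.approx(np.mean(rs_ref), abs=1e-12)
        assert np.mean(rs) < -0.2

    def test_subject_order_invariance(self, rng):
        x = rng.normal(size=(15, 2))
        y = 0.1 + x @ np.array([1.0, -0.5]) + rng.normal(0, 0.1, 15)
        m1 = loocv(x, y)
        perm = rng.permutation(15)
        m2 = loocv(x[perm], y[perm])
        assert m2.r == pytest.approx(m1.r)
        assert m2.rmse == pytest.approx(m1.rmse)
        assert np.allclose(m2.loocv_predictions, m1.loocv_predictions[perm])

    def test_tolerance_is_reciprocal_vif(self, rng):
        x = rng.normal(size=(30, 3))
        y = x @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.5, 30)
        model = loocv(x, y)
        assert np.allclose(model.tolerance, 1.0 / model.vif)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv(rng.normal(size=(2, 1)), np.array([1.0, 2.0]))


class TestBackwardElimination:
    def test_keeps_only_informative_feature(self, rng):
        import pandas as pd

        x = pd.DataFrame(rng.normal(size=(40, 4)),
                         columns=["delta_clu", "delta_le", "delta_ge", "delta_l"])
        y = 0.2 - 2.0 * x["delta_l"].to_numpy() + rng.normal(0, 0.05, 40)
        kept = backward_eliminate(x, y)
        assert "delta_l" in kept
        assert len(kept) <= 2
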