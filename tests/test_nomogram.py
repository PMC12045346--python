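"""Nomogram construction/round-trip, time-dependent AUC, stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from mhlkit.nomogram import (NomogramSpec, build_nomogram, predict_survival,
                             stepwise_select, time_dependent_auc)
from mhlkit.survival import cox_multivariable

from .test_survival import simulate_cox


def fitted_example(seed=0, n=120):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.uniform(10, 40, n)
    t = rng.exponential(20.0, n) / np.exp(0.9 * x1 - 0.05 * x2)
    c = rng.uniform(5, 60, n)
    df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)},
                      index=[f"p{i}" for i in range(n)])
    X = pd.DataFrame({"x1": x1, "x2": x2}, index=df.index)
    fit = cox_multivariable(X, df)
    return fit, X, df


class TestNomogram:
    def test_round_trip_matches_direct_cox(self):
        """Nomogram-read survival equals the direct Cox prediction for every
        fitted patient at every horizon."""
        fit, X, df = fitted_example()
        spec = build_nomogram(fit, X, horizons=(6, 12, 24))
        for t in (6.0, 12.0, 24.0):
            direct = fit.predict_survival(X, t)
            via_chart = np.array([predict_survival(spec, row, t)
                                  for _, row in X.iterrows()])
            assert np.max(np.abs(via_chart - direct.to_numpy())) < 1e-6

    def test_round_trip_matches_lifelines_predictor(self):
        # compared on the baseline grid: off-grid, lifelines interpolates
        # linearly whereas the chart uses the Breslow step function
        fit, X, df = fitted_example(seed=1)
        spec = build_nomogram(fit, X)
        grid = fit.baseline_survival.index
        times = [float(grid[len(grid) // 4]), float(grid[len(grid) // 2])]
        ll = fit.fitter.predict_survival_function(X, times=times)
        for j, t in enumerate(times):
            via_chart = np.array([predict_survival(spec, row, t)
                                  for _, row in X.iterrows()])
            assert np.max(np.abs(via_chart - ll.iloc[j].to_numpy())) < 1e-6

    def test_points_geometry(self):
        fit, X, df = fitted_example(seed=2)
        spec = build_nomogram(fit, X)
        # every point value within range is non-negative
        for p in spec.predictors:
            lo, hi = spec.ranges[p]
            assert spec.points(p, lo) >= -1e-12 and spec.points(p, hi) >= -1e-12
        # exactly one predictor attains 100 at its range extreme
        maxima = [max(spec.points(p, spec.ranges[p][0]),
                      spec.points(p, spec.ranges[p][1]))
                  for p in spec.predictors]
        assert sum(abs(m - 100.0) < 1e-9 for m in maxima) == 1
        # min-vs-max difference on one predictor equals its full scale
        p = spec.predictors[0]
        lo, hi = spec.ranges[p]
        a, b = dict(X.iloc[0]), dict(X.iloc[0])
        a[p], b[p] = lo, hi
        assert abs(spec.total_points(b) - spec.total_points(a)) == pytest.approx(
            abs(spec.points(p, hi) - spec.points(p, lo)), abs=1e-9)

    def test_single_predictor_spans_0_100_and_is_monotone_bijection(self):
        rng = np.random.default_rng(3)
        df = simulate_cox(rng, n=100, beta=1.0)
        fit = cox_multivariable(df[["x"]], df)
        spec = build_nomogram(fit, df[["x"]])
        lo, hi = spec.ranges["x"]
        assert {round(spec.points("x", lo), 9), round(spec.points("x", hi), 9)} \
            == {0.0, 100.0}
        xs = np.linspace(lo, hi, 20)
        tps = [spec.total_points({"x": x}) for x in xs]
        lps = [spec.lp_from_points(tp) for tp in tps]
        assert np.all(np.diff(tps) > 0) or np.all(np.diff(tps) < 0)
        assert np.allclose(lps, float(fit.beta["x"]) * xs, atol=1e-9)

    def test_predict_survival_boundaries(self):
        fit, X, df = fitted_example(seed=4)
        spec = build_nomogram(fit, X)
        patient = dict(X.iloc[0])
        assert predict_survival(spec, patient, 0.0) == 1.0
        s6, s12, s24 = (predict_survival(spec, patient, t) for t in (6, 12, 24))
        assert 1 >= s6 >= s12 >= s24 >= 0

    def test_mean_covariate_patient_reads_baseline(self):
        fit, X, df = fitted_example(seed=5)
        spec = build_nomogram(fit, X)
        mean_patient = {p: float(X[p].mean()) for p in spec.predictors}
        t = float(fit.baseline_survival.index[len(fit.baseline_survival) // 2])
        s0 = spec.baseline_at(t)
        assert predict_survival(spec, mean_patient, t) == pytest.approx(s0, abs=1e-9)

    def test_out_of_range_covariate_clipped_with_warning(self):
        fit, X, df = fitted_example(seed=6)
        spec = build_nomogram(fit, X)
        patient = dict(X.iloc[0])
        patient["x1"] = X["x1"].max() + 100.0
        with pytest.warns(UserWarning, match="outside fitted range"):
            v = predict_survival(spec, patient, 12.0)
        clipped = dict(patient, x1=X["x1"].max())
        assert v == pytest.approx(predict_survival(spec, clipped, 12.0))

    def test_zero_range_predictor_rejected(self):
        fit, X, df = fitted_example(seed=7)
        X2 = X.copy()
        X2["x1"] = X2["x1"].iloc[0]
        with pytest.raises(ValueError, match="zero observed range"):
            build_nomogram(fit, X2)

    def test_json_round_trip(self, tmp_path):
        fit, X, df = fitted_example(seed=8)
        spec = build_nomogram(fit, X)
        spec.to_json(tmp_path / "n.json")
        back = NomogramSpec.from_json(tmp_path / "n.json")
        patient = dict(X.iloc[3])
        assert predict_survival(back, patient, 12.0) == pytest.approx(
            predict_survival(spec, patient, 12.0), abs=1e-12)


def rank_sum_auc(scores, cases, controls):
    s_case, s_ctrl = scores[cases], scores[controls]
    gt = (s_case[:, None] > s_ctrl[None, :]).sum()
    eq = (s_case[:, None] == s_ctrl[None, :]).sum()
    return (gt + 0.5 * eq) / (len(s_case) * len(s_ctrl))


class TestTimeDependentAUC:
    def test_uncensored_reduces_to_rank_sum(self):
        rng = np.random.default_rng(0)
        n = 80
        time = rng.exponential(10, n)
        scores = pd.Series(rng.normal(0, 1, n))
        surv = pd.DataFrame({"time": time, "event": 1}, index=scores.index)
        t = float(np.median(time))
        roc = time_dependent_auc(scores, surv, t)
        oracle = rank_sum_auc(scores.to_numpy(), time <= t, time > t)
        assert roc.auc == pytest.approx(oracle, abs=1e-12)

    def test_perfect_ranking_gives_auc_one(self):
        n = 50
        time = np.linspace(1, 50, n)
        scores = pd.Series(-time)  # higher score = earlier event
        surv = pd.DataFrame({"time": time, "event": 1}, index=scores.index)
        assert time_dependent_auc(scores, surv, 25.0).auc == pytest.approx(1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        n = 60
        time = rng.exponential(10, n)
        event = (rng.random(n) < 0.7).astype(int)
        scores = pd.Series(rng.normal(0, 1, n))
        surv = pd.DataFrame({"time": time, "event": event}, index=scores.index)
        a = time_dependent_auc(scores, surv, 8.0).auc
        b = time_dependent_auc(np.exp(3 * scores), surv, 8.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_scikit_survival_under_censoring(self):
        """Independent cross-check of the IPCW estimator."""
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(0, 1, n)
        t = rng.exponential(10, n) / np.exp(0.8 * x)
        c = rng.uniform(0, 25, n)
        time, event = np.minimum(t, c), (t <= c)
        scores = pd.Series(x)
        surv = pd.DataFrame({"time": time, "event": event.astype(int)},
                            index=scores.index)
        y = Surv.from_arrays(event, time)
        for horizon in (5.0, 10.0):
            ours = time_dependent_auc(scores, surv, horizon).auc
            theirs, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, x, [horizon])
            assert ours == pytest.approx(float(theirs[0]), abs=5e-2)

    def test_no_cases_or_controls_undefined(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        surv = pd.DataFrame({"time": [10, 11, 12], "event": [0, 0, 0]},
                            index=scores.index)
        assert np.isnan(time_dependent_auc(scores, surv, 5.0).auc)
        assert np.isnan(time_dependent_auc(scores, surv, 50.0).auc)


class TestStepwise:
    def test_noise_candidate_eliminated(self):
        rng = np.random.default_rng(3)
        kept_noise = 0
        for _ in range(25):
            df = simulate_cox(rng, n=150, beta=1.0)
            X = pd.DataFrame({"x": df["x"], "noise": rng.normal(0, 1, len(df))},
                             index=df.index)
            fit = stepwise_select(X, df)
            assert "x" in fit.covariates
            kept_noise += "noise" in fit.covariates
        assert kept_noise <= 3  # ~alpha of the replicates at most

    def test_single_planted_candidate_retained(self):
        rng = np.random.default_rng(4)
        df = simulate_cox(rng, n=200, beta=1.0)
        fit = stepwise_select(df[["x"]], df)
        assert fit.covariates == ["x"]

    def test_collinear_duplicate_dropped_first_by_order(self):
        rng = np.random.default_rng(5)
        df = simulate_cox(rng, n=150, beta=1.0)
        X = pd.DataFrame({"a": df["x"], "b": df["x"] * 2.0}, index=df.index)
        fit = stepwise_select(X, df)
        assert fit.covariates == ["a"]

    def test_pure_noise_everything_eliminated(self):
        rng = np.random.default_rng(6)
        df = simulate_cox(rng, n=100, beta=0.0)
        X = pd.DataFrame({"n1": rng.normal(0, 1, len(df))}, index=df.index)
        fit = stepwise_select(X, df, alpha_enter=1e-6)
        assert fit.covariates == [] and not fit.converged

    def test_forward_matches_backward_on_clear_signal(self):
        rng = np.random.default_rng(7)
        df = simulate_cox(rng, n=250, beta=1.2)
        X = pd.DataFrame({"x": df["x"], "noise": rng.normal(0, 1, len(df))},
                         index=df.index)
        bwd = stepwise_select(X, df, direction="backward")
        fwd = stepwise_select(X, df, direction="forward")
        assert "x" in bwd.covariates and "x" in fwd.covariates
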