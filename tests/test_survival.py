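"""Cox screening, panel selection, composite/risk scores, KM/log-rank,
ctDNA-fraction correlation screen."""

import numpy as np
import pandas as pd
import pytest

from mhlkit.blocks import MHB
from mhlkit.survival import (CorrelationScreenError, composite_score,
                             cox_univariate, ctdna_correlation_screen,
                             km_logrank, median_split, risk_score, select_panel)

from .conftest import block_of, region_of


def simulate_cox(rng, n=120, beta=0.8, censor=3.0):
    x = rng.normal(0, 1, n)
    t = rng.exponential(1.0, n) / np.exp(beta * x)
    c = rng.uniform(0, censor, n)
    return pd.DataFrame({
        "time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x,
    }, index=[f"p{i}" for i in range(n)])


class TestCoxUnivariate:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        betas = []
        for _ in range(15):
            df = simulate_cox(rng, n=200, beta=0.8)
            fit = cox_univariate(df["x"], df)
            betas.append(float(fit.beta.iloc[0]))
        assert abs(np.mean(betas) - 0.8) < 0.1

    def test_affine_equivariance(self):
        rng = np.random.default_rng(1)
        df = simulate_cox(rng)
        fit1 = cox_univariate(df["x"], df)
        fit2 = cox_univariate((df["x"] * 2).rename("x2"), df)
        assert float(fit2.beta.iloc[0]) == pytest.approx(
            float(fit1.beta.iloc[0]) / 2, rel=1e-6)
        # linear predictor (hence patient ranking) unchanged
        lp1 = df["x"] * float(fit1.beta.iloc[0])
        lp2 = df["x"] * 2 * float(fit2.beta.iloc[0])
        assert np.allclose(lp1, lp2, rtol=1e-6)

    def test_hr_is_exp_beta_and_ci_brackets(self):
        rng = np.random.default_rng(2)
        df = simulate_cox(rng)
        fit = cox_univariate(df["x"], df)
        s = fit.summary.iloc[0]
        assert s["hr"] == pytest.approx(np.exp(s["beta"]), rel=1e-12)
        assert s["ci_low"] <= s["hr"] <= s["ci_high"]

    def test_constant_covariate_flagged(self):
        rng = np.random.default_rng(3)
        df = simulate_cox(rng)
        fit = cox_univariate(pd.Series(1.0, index=df.index, name="c"), df)
        assert not fit.converged

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 0],
                           "x": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            cox_univariate(df["x"], df)


def fake_fit(beta, p):
    from mhlkit.survival import CoxFit
    summary = pd.DataFrame({"beta": [beta], "hr": [np.exp(beta)],
                            "ci_low": [np.nan], "ci_high": [np.nan], "p": [p]})
    return CoxFit(summary, pd.Series(dtype=float), 0.0, True, 10, 5)


class TestSelectPanel:
    def make_blocks(self, genes):
        blocks = {}
        region_cache = {}
        for i, gene in enumerate(genes):
            region = region_cache.setdefault(gene, region_of(40, name=gene,
                                                             start=1000 * (i + 1)))
            idx = sum(1 for g in genes[:i] if g == gene)
            blocks[f"{gene}:{idx}"] = block_of(region, idx * 4, idx * 4 + 3,
                                               name=f"{gene}:{idx}")
        return blocks

    def test_gene_collapse_keeps_highest_hr(self):
        genes = ["g1", "g1", "g2", "g3"]
        blocks = self.make_blocks(genes)
        fits = {"g1:0": fake_fit(0.5, 0.01), "g1:1": fake_fit(1.2, 0.02),
                "g2:0": fake_fit(0.8, 0.03), "g3:0": fake_fit(0.1, 0.2)}
        ranking = {"g1:0": 0.001, "g1:1": 0.002, "g2:0": 0.003, "g3:0": 0.004}
        panel = select_panel(list(fits), fits, blocks, ranking, top_k=20)
        # g3 fails Cox alpha; g1 collapses to its higher-HR member
        assert set(panel) == {"g1:1", "g2:0"}

    def test_distinct_genes_panel_is_top_k(self):
        genes = ["a", "b", "c", "d"]
        blocks = self.make_blocks(genes)
        fits = {f"{g}:0": fake_fit(0.5, 0.01) for g in genes}
        ranking = {f"{g}:0": i for i, g in enumerate(genes)}
        panel = select_panel(list(fits), fits, blocks, ranking, top_k=3)
        assert len(panel) == 3 and "d:0" not in panel

    def test_equal_hr_tie_breaks_leftmost(self):
        region = region_of(40, name="g", start=1000)
        blocks = {"g:0": block_of(region, 0, 3, name="g:0"),
                  "g:1": block_of(region, 8, 11, name="g:1")}
        fits = {"g:0": fake_fit(0.7, 0.01), "g:1": fake_fit(0.7, 0.02)}
        ranking = {"g:0": 0.5, "g:1": 0.1}   # ranking must not affect the tie
        panel = select_panel(["g:0", "g:1"], fits, blocks, ranking, top_k=5)
        assert panel == ["g:0"]


class TestScores:
    def test_composite_hand_arithmetic(self):
        fits = {"m1": fake_fit(0.5, 0.01), "m2": fake_fit(-1.0, 0.01),
                "m3": fake_fit(2.0, 0.01)}
        vals = pd.DataFrame({"m1": [0.1, 0.0], "m2": [0.2, 1.0],
                             "m3": [0.3, 0.5]}, index=["a", "b"])
        C = composite_score(["m1", "m2", "m3"], fits, vals)
        assert C["a"] == pytest.approx(0.5 * 0.1 - 1.0 * 0.2 + 2.0 * 0.3)
        assert C["b"] == pytest.approx(-1.0 * 1.0 + 2.0 * 0.5)

    def test_all_zero_matrix_gives_zero_scores(self):
        fits = {"m1": fake_fit(0.5, 0.01)}
        vals = pd.DataFrame({"m1": [0.0, 0.0, 0.0]})
        assert (composite_score(["m1"], fits, vals) == 0).all()

    def test_median_split_sizes_and_tie_rule(self):
        rng = np.random.default_rng(4)
        for n in (7, 8, 49):
            s = pd.Series(rng.normal(size=n))
            labels, med = median_split(s)
            n_high = int((labels == "high").sum())
            assert n_high == n // 2  # ties (the median itself) go low
        # explicit tie at the median
        labels, _ = median_split(pd.Series([1.0, 2.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_risk_score_composite_only_preserves_ranking(self):
        rng = np.random.default_rng(5)
        df = simulate_cox(rng, n=80, beta=1.0)
        comp = df["x"].rename("composite_score").to_frame()
        rs = risk_score(comp, df)
        assert (rs.scores.rank() == df["x"].rank()).all() or \
               (rs.scores.rank() == (-df["x"]).rank()).all()

    def test_constant_component_dropped_with_fit_still_reported(self):
        rng = np.random.default_rng(6)
        df = simulate_cox(rng, n=80, beta=1.0)
        comps = pd.DataFrame({"x": df["x"], "const": 1.0}, index=df.index)
        rs = risk_score(comps, df)
        assert rs.fit.covariates == ["x"]

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        b1s, b2s = [], []
        for _ in range(10):
            n = 300
            x1 = rng.normal(0, 1, n)
            x2 = rng.normal(0, 1, n)
            t = rng.exponential(1.0, n) / np.exp(0.7 * x1 - 0.4 * x2)
            df = pd.DataFrame({"time": np.minimum(t, 3.0),
                               "event": (t <= 3.0).astype(int)},
                              index=[f"p{i}" for i in range(n)])
            comps = pd.DataFrame({"x1": x1, "x2": x2}, index=df.index)
            rs = risk_score(comps, df)
            b1s.append(float(rs.fit.beta["x1"]))
            b2s.append(float(rs.fit.beta["x2"]))
        assert abs(np.mean(b1s) - 0.7) < 0.1
        assert abs(np.mean(b2s) + 0.4) < 0.1


def logrank_oracle(time, event, group):
    """Hand Mantel-Haenszel O-E statistic (no tied event times assumed)."""
    order = np.argsort(time)
    time, event, group = time[order], event[order], group[order]
    U = V = 0.0
    for i in np.flatnonzero(event == 1):
        at_risk = time >= time[i]
        n = at_risk.sum()
        n1 = (group[at_risk] == 1).sum()
        e = n1 / n
        U += (group[i] == 1) - e
        if n > 1:
            V += e * (1 - e)
    return U * U / V


def cox_score_test_binary(time, event, group):
    """Cox partial-likelihood score test for a binary covariate — identical
    to the log-rank statistic when event times are untied."""
    return logrank_oracle(time, event, group)  # same formula without ties


class TestKMLogrank:
    def test_identical_groups_p_near_one(self):
        time = np.array([5, 8, 12, 20, 30, 5, 8, 12, 20, 30], dtype=float)
        event = np.array([1, 1, 0, 1, 0] * 2)
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        surv = pd.DataFrame({"time": time, "event": event}, index=labels.index)
        km = km_logrank(labels, surv)
        assert km["logrank_p"] > 0.9
        assert km["median_survival"]["a"] == km["median_survival"]["b"]

    def test_textbook_oracle_agreement(self):
        rng = np.random.default_rng(8)
        time = rng.exponential(10, 40) + rng.uniform(0, 1e-6, 40)  # untied
        group = (rng.random(40) < 0.5).astype(int)
        time[group == 1] *= 0.5
        event = (rng.random(40) < 0.8).astype(int)
        labels = pd.Series(np.where(group == 1, "hi", "lo"))
        surv = pd.DataFrame({"time": time, "event": event}, index=labels.index)
        km = km_logrank(labels, surv)
        assert km["logrank_stat"] == pytest.approx(
            logrank_oracle(time, event, group), rel=1e-6)

    def test_no_event_group_median_not_reached(self):
        labels = pd.Series(["a"] * 4 + ["b"] * 4)
        surv = pd.DataFrame({"time": [1, 2, 3, 4, 10, 11, 12, 13],
                             "event": [1, 1, 1, 1, 0, 0, 0, 0]},
                            index=labels.index)
        km = km_logrank(labels, surv)
        assert np.isnan(km["median_survival"]["b"])
        assert km["median_survival"]["a"] == pytest.approx(2.5, abs=1.0)


class TestCorrelationScreen:
    def eligible_frame(self, n=20, n_cols=1, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n)]
        fr = pd.Series(np.linspace(0.02, 0.6, n), index=idx, name="f")
        vals = pd.DataFrame(rng.uniform(0, 1, size=(n, n_cols)), index=idx,
                            columns=[f"b{j}" for j in range(n_cols)])
        return vals, fr

    def test_exact_linear_function_flagged_r1(self):
        vals, fr = self.eligible_frame()
        vals["lin"] = 0.1 + 0.5 * fr
        out = ctdna_correlation_screen(vals, fr)
        row = out.set_index("mhb_id").loc["lin"]
        assert row["r"] == pytest.approx(1.0, abs=1e-12) and row["flagged"]

    def test_low_fraction_patients_excluded(self):
        vals, fr = self.eligible_frame(n=20)
        fr.iloc[:8] = 0.005        # at or below the 1% band
        fr.iloc[8] = 0.01          # boundary: excluded (strictly greater kept)
        out = ctdna_correlation_screen(vals, fr)
        assert out.attrs["n_eligible"] == 11
        assert out.attrs["n_excluded"] == 9
        assert (out["n"] <= 11).all()

    def test_column_with_excess_missingness_skipped(self):
        vals, fr = self.eligible_frame(n=20, n_cols=2)
        vals.iloc[:12, 0] = np.nan   # 60% missing among eligible
        out = ctdna_correlation_screen(vals, fr)
        assert list(out["mhb_id"]) == ["b1"]

    def test_too_few_eligible_aborts(self):
        vals, fr = self.eligible_frame(n=5)
        fr[:] = 0.005
        with pytest.raises(CorrelationScreenError):
            ctdna_correlation_screen(vals, fr)
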