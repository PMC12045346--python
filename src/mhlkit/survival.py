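"""Survival modelling: Cox screening, composite and multi-modal risk scores.

The prognostic construction is: (1) univariate Cox proportional-hazards fits
of overall survival on each candidate MHB's MHL; (2) a reduced panel —
significant DMRs ranked by differential strength, truncated to ``top_k`` and
collapsed to one MHB per gene region keeping the highest hazard ratio;
(3) a composite score C = sum_i beta_i * M_i over the panel (univariate Cox
coefficients times MHL values); (4) a multivariable risk score
R = sum_j beta_j * x_j over the composite, log2-transformed clinical
biomarkers and the predicted ctDNA fraction (raw 0-1 scale); (5) a median
split of R into high/low risk groups compared by Kaplan-Meier / log-rank.

Cox fits use lifelines (Efron tie handling). All scores are deterministic
linear functionals of their inputs and invariant to patient ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .blocks import MHB

__all__ = [
    "CoxFit",
    "cox_univariate",
    "cox_multivariable",
    "select_panel",
    "composite_score",
    "RiskScore",
    "risk_score",
    "km_logrank",
    "ctdna_correlation_screen",
    "CorrelationScreenError",
]

logger = logging.getLogger(__name__)

CLINICAL_LOG2 = ("psa", "ldh", "alp", "albumin", "hemoglobin")


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate with columns beta, hr, ci_low,
    ci_high, p (Wald, 95% CI); ``baseline_survival`` is the Breslow-derived
    baseline survival function evaluated at the normalized covariate mean,
    so S(t | x) = S0(t) ** exp(lp(x) - mean_lp).
    """

    summary: pd.DataFrame
    baseline_survival: pd.Series
    mean_lp: float
    converged: bool
    n: int
    n_events: int
    fitter: CoxPHFitter | None = field(default=None, repr=False)

    @property
    def beta(self) -> pd.Series:
        return self.summary["beta"]

    @property
    def covariates(self) -> list[str]:
        return list(self.summary.index)

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        return X[self.covariates] @ self.beta

    def predict_survival(self, X: pd.DataFrame, t: float) -> pd.Series:
        """Direct Cox survival prediction S(t | x) via the Breslow baseline."""
        s0 = baseline_at(self.baseline_survival, t)
        lp = self.linear_predictor(X)
        return s0 ** np.exp(lp - self.mean_lp)


def baseline_at(baseline: pd.Series, t: float) -> float:
    """Step interpolation of a baseline survival table: S0(0) = 1, value of
    the largest tabulated time <= t, last value beyond support."""
    times = baseline.index.to_numpy(dtype=float)
    idx = np.searchsorted(times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(baseline.iloc[idx])


def _fit_cox(df: pd.DataFrame, covariates: Sequence[str],
             time_col: str = "time", event_col: str = "event") -> CoxFit:
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[[time_col, event_col, *covariates]],
                    duration_col=time_col, event_col=event_col)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("Cox fit failed for %s: %s", list(covariates), exc)
            summary = pd.DataFrame(
                np.nan, index=list(covariates),
                columns=["beta", "hr", "ci_low", "ci_high", "p"])
            return CoxFit(summary, pd.Series(dtype=float), np.nan, False,
                          len(df), int(df[event_col].sum()))
    s = cph.summary
    summary = pd.DataFrame({
        "beta": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    summary.index = list(covariates)
    baseline = cph.baseline_survival_.iloc[:, 0]
    mean_lp = float(np.asarray(cph._norm_mean[covariates]) @ summary["beta"].to_numpy())
    return CoxFit(summary, baseline, mean_lp, converged, len(df),
                  int(df[event_col].sum()), fitter=cph)


def cox_univariate(values: pd.Series, survival: pd.DataFrame) -> CoxFit:
    """Univariate Cox PH fit of survival on one covariate.

    ``survival`` needs columns ``time`` (months, > 0) and ``event`` (1 =
    death). Requires >= 2 events and a non-constant covariate; non-converged
    or degenerate fits come back flagged (``converged=False``) so callers can
    exclude them from selection.
    """
    name = values.name or "x"
    df = survival[["time", "event"]].copy()
    df[name] = values.reindex(df.index)
    df = df.dropna()
    if int(df["event"].sum()) < 2:
        raise ValueError("need >= 2 events for a Cox fit")
    if float(df[name].std()) == 0.0:
        logger.warning("covariate %s is constant; flagged fit", name)
        summary = pd.DataFrame(np.nan, index=[name],
                               columns=["beta", "hr", "ci_low", "ci_high", "p"])
        return CoxFit(summary, pd.Series(dtype=float), np.nan, False,
                      len(df), int(df["event"].sum()))
    return _fit_cox(df, [name])


def cox_multivariable(X: pd.DataFrame, survival: pd.DataFrame) -> CoxFit:
    """Multivariable Cox PH fit (constant columns dropped with a warning)."""
    X = X.reindex(survival.index)
    keep = [c for c in X.columns if float(X[c].std()) > 0.0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant covariates: %s", dropped)
    if not keep:
        raise ValueError("no non-constant covariates")
    df = pd.concat([survival[["time", "event"]], X[keep]], axis=1).dropna()
    return _fit_cox(df, keep)


def select_panel(candidates: Sequence[str], fits: Mapping[str, CoxFit],
                 blocks: Mapping[str, MHB], ranking: Mapping[str, float],
                 top_k: int = 20, alpha: float = 0.05) -> list[str]:
    """Reduce candidate DMRs to a prognostic panel.

    Candidates with a converged univariate Cox fit at p < alpha are ordered
    by ``ranking`` (ascending; e.g. the mHSPC-vs-mCRPC differential p-value),
    truncated to ``top_k`` (fewer available -> use all, warn), then collapsed
    to one MHB per gene region keeping the highest hazard ratio; ties break
    deterministically to the leftmost genomic position.
    """
    sig = []
    for c in candidates:
        fit = fits.get(c)
        if fit is None or not fit.converged:
            continue
        p = float(fit.summary["p"].iloc[0])
        if np.isfinite(p) and p < alpha:
            sig.append(c)
    sig.sort(key=lambda c: (ranking.get(c, np.inf), c))
    if len(sig) < top_k:
        logger.warning("select_panel: only %d significant candidates (< top_k=%d)",
                       len(sig), top_k)
    top = sig[:top_k]
    best: dict[str, str] = {}
    for c in top:
        gene = blocks[c].region_name
        if gene not in best:
            best[gene] = c
            continue
        prev = best[gene]
        hr_c = float(fits[c].summary["hr"].iloc[0])
        hr_p = float(fits[prev].summary["hr"].iloc[0])
        if hr_c > hr_p or (hr_c == hr_p and blocks[c].start < blocks[prev].start):
            best[gene] = c
    panel = sorted(best.values(), key=lambda c: (blocks[c].chrom, blocks[c].start))
    logger.info("select_panel: %d candidates -> top %d -> %d per-gene representatives",
                len(sig), len(top), len(panel))
    return panel


def composite_score(panel: Sequence[str], fits: Mapping[str, CoxFit],
                    values: pd.DataFrame) -> pd.Series:
    """Composite score C = sum_i beta_i * M_i over the panel MHBs."""
    if not panel:
        raise ValueError("empty panel")
    betas = np.array([float(fits[c].summary["beta"].iloc[0]) for c in panel])
    C = values[list(panel)].to_numpy() @ betas
    return pd.Series(C, index=values.index, name="composite_score")


@dataclass
class RiskScore:
    """Multivariable risk score with its median-split group labels."""

    scores: pd.Series
    labels: pd.Series  # "high" / "low"
    median: float
    fit: CoxFit


def median_split(scores: pd.Series) -> tuple[pd.Series, float]:
    """High/low labels from the median: strictly greater -> high (ties low)."""
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"),
                       index=scores.index, name="risk_group")
    return labels, med


def risk_score(components: pd.DataFrame, survival: pd.DataFrame) -> RiskScore:
    """Multivariable Cox on the supplied components; R = X @ beta.

    Components are used as given — clinical biomarkers should already be
    log2-transformed (see :func:`log2_clinical`); predicted ctDNA fraction
    enters on its raw 0-1 scale. Patients with score strictly above the
    median are labelled high-risk.
    """
    fit = cox_multivariable(components, survival)
    X = components[fit.covariates].reindex(survival.index)
    scores = (X @ fit.beta).rename("risk_score")
    labels, med = median_split(scores)
    return RiskScore(scores, labels, med, fit)


def log2_clinical(clinical: pd.DataFrame,
                  columns: Sequence[str] = CLINICAL_LOG2) -> pd.DataFrame:
    """log2-transform positive-valued clinical biomarkers (prefix log2_)."""
    out = {}
    for c in columns:
        if c in clinical.columns:
            out[f"log2_{c}"] = np.log2(clinical[c])
    return pd.DataFrame(out, index=clinical.index)


def km_logrank(labels: pd.Series, survival: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns per-group product-limit curves, the median survival (NaN =
    not reached), and the log-rank chi-square statistic and p-value.
    """
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    curves, medians, masks = {}, {}, {}
    for g in groups:
        idx = labels.index[labels == g]
        sub = survival.loc[idx].dropna()
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_.iloc[:, 0]
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
        masks[g] = sub
    res = logrank_test(masks[groups[0]]["time"], masks[groups[1]]["time"],
                       masks[groups[0]]["event"], masks[groups[1]]["event"])
    return {
        "groups": groups,
        "curves": curves,
        "median_survival": medians,
        "logrank_stat": float(res.test_statistic),
        "logrank_p": float(res.p_value),
    }


class CorrelationScreenError(RuntimeError):
    """Raised when too few patients remain for the ctDNA correlation screen."""


def ctdna_correlation_screen(values: pd.DataFrame, fractions: pd.Series,
                             min_fraction: float = 0.01,
                             min_nonmissing: float = 0.5,
                             r_cutoff: float = 0.5,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each MHB's MHL with predicted ctDNA fraction.

    Patients at fraction <= ``min_fraction`` (the 0-1% band, where the
    predictor is unreliable) are excluded first. Each MHB with more than
    ``min_nonmissing`` observed values among the eligible patients is
    correlated against fraction; MHBs with r > r_cutoff and p < alpha are
    flagged. ``values`` should be the *pre-imputation* matrix so that
    missingness is respected. The result carries ``attrs``:
    n_eligible, n_excluded, n_screened, n_flagged, passing_fraction.
    """
    fractions = fractions.reindex(values.index).dropna()
    eligible = fractions.index[fractions > min_fraction]
    n_excluded = int(len(fractions) - len(eligible))
    if len(eligible) < 3:
        raise CorrelationScreenError(
            f"only {len(eligible)} patients with ctDNA fraction > {min_fraction:g}; "
            "need >= 3 for a correlation screen")
    sub = values.loc[eligible]
    f = fractions.loc[eligible]
    rows = []
    for col in sub.columns:
        v = sub[col]
        obs = v.notna()
        if obs.mean() <= min_nonmissing:
            continue
        vv, ff = v[obs], f[obs]
        if float(vv.std()) == 0.0 or float(ff.std()) == 0.0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(vv, ff)
        flagged = bool(np.isfinite(r) and r > r_cutoff and p < alpha)
        rows.append({"mhb_id": col, "n": int(obs.sum()), "r": float(r),
                     "p_value": float(p), "flagged": flagged})
    out = pd.DataFrame(rows, columns=["mhb_id", "n", "r", "p_value", "flagged"])
    out.attrs.update({
        "n_eligible": int(len(eligible)),
        "n_excluded": n_excluded,
        "n_screened": int(len(out)),
        "n_flagged": int(out["flagged"].sum()) if len(out) else 0,
        "passing_fraction": float(out["flagged"].mean()) if len(out) else float("nan"),
    })
    return out
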