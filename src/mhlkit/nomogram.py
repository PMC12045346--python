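"""Survival nomograms and time-dependent ROC evaluation.

A nomogram turns a multivariable Cox model into a score chart: each
predictor j with coefficient beta_j and observed range [min_j, max_j] is
mapped affinely to points

    p_j(x) = 100 * beta_j * (x - x_ref_j) / scale,
    scale  = max_j |beta_j| * (max_j - min_j),

with x_ref_j the range end minimizing beta_j * x, so points are non-negative
and exactly one predictor spans 0-100. Total points are an affine bijection
of the Cox linear predictor, so survival probabilities read off the chart,

    S(t | x) = S0(t) ** exp(lp(x) - mean_lp),

agree with the direct Cox prediction exactly (the exact affine maps are used
for probability lookups; the 1-point tabulation exists only for rendering).

Model performance at a horizon t uses the cumulative-case / dynamic-control
time-dependent ROC AUC with inverse-probability-of-censoring weights (IPCW,
Kaplan-Meier censoring estimator): cases are patients with an observed event
by t, controls are patients still at risk past t. With no censoring this
reduces to the plain rank-sum AUC of cases versus survivors.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import CoxFit, baseline_at, cox_multivariable

__all__ = [
    "NomogramSpec",
    "TimeROC",
    "build_nomogram",
    "predict_survival",
    "time_dependent_auc",
    "stepwise_select",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (6.0, 12.0, 24.0)


@dataclass
class NomogramSpec:
    """Serializable nomogram: point maps plus the baseline survival table."""

    predictors: list[str]
    betas: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    refs: dict[str, float]          # range end minimizing beta * x
    scale: float                    # max_j |beta_j| * range_j
    lp_ref: float                   # sum_j beta_j * x_ref_j
    mean_lp: float
    baseline_times: list[float]
    baseline_survival: list[float]
    horizons: tuple[float, ...] = DEFAULT_HORIZONS

    def points(self, predictor: str, x: float) -> float:
        b = self.betas[predictor]
        return 100.0 * b * (x - self.refs[predictor]) / self.scale

    def total_points(self, patient: Mapping[str, float]) -> float:
        return sum(self.points(p, float(patient[p])) for p in self.predictors)

    def lp_from_points(self, total_points: float) -> float:
        return self.lp_ref + total_points * self.scale / 100.0

    def baseline_at(self, t: float) -> float:
        s = pd.Series(self.baseline_survival, index=self.baseline_times)
        return baseline_at(s, t)

    def to_json(self, path) -> None:
        payload = {
            "predictors": self.predictors,
            "betas": self.betas,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "refs": self.refs,
            "scale": self.scale,
            "lp_ref": self.lp_ref,
            "mean_lp": self.mean_lp,
            "baseline_times": self.baseline_times,
            "baseline_survival": self.baseline_survival,
            "horizons": list(self.horizons),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NomogramSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            predictors=d["predictors"], betas=d["betas"],
            ranges={k: tuple(v) for k, v in d["ranges"].items()},
            refs=d["refs"], scale=d["scale"], lp_ref=d["lp_ref"],
            mean_lp=d["mean_lp"], baseline_times=d["baseline_times"],
            baseline_survival=d["baseline_survival"],
            horizons=tuple(d["horizons"]),
        )


@dataclass(frozen=True)
class TimeROC:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int
    scheme: str = "ipcw-km"


def build_nomogram(fit: CoxFit, data: pd.DataFrame,
                   horizons: Sequence[float] = DEFAULT_HORIZONS) -> NomogramSpec:
    """Derive nomogram point scales from a converged multivariable Cox fit.

    ``data`` defines each predictor's observed range; a zero-range predictor
    is rejected (it carries no points and signals a degenerate fit).
    """
    if not fit.converged:
        raise ValueError("cannot build a nomogram from a non-converged fit")
    betas = {p: float(fit.beta[p]) for p in fit.covariates}
    ranges, refs = {}, {}
    scale = 0.0
    for p in fit.covariates:
        lo, hi = float(data[p].min()), float(data[p].max())
        if hi <= lo:
            raise ValueError(f"predictor {p!r} has zero observed range")
        ranges[p] = (lo, hi)
        refs[p] = lo if betas[p] >= 0 else hi
        scale = max(scale, abs(betas[p]) * (hi - lo))
    lp_ref = sum(betas[p] * refs[p] for p in fit.covariates)
    baseline = fit.baseline_survival
    return NomogramSpec(
        predictors=list(fit.covariates), betas=betas, ranges=ranges, refs=refs,
        scale=scale, lp_ref=lp_ref, mean_lp=fit.mean_lp,
        baseline_times=[float(t) for t in baseline.index],
        baseline_survival=[float(v) for v in baseline.to_numpy()],
        horizons=tuple(float(h) for h in horizons),
    )


def predict_survival(spec: NomogramSpec, patient: Mapping[str, float], t: float) -> float:
    """Survival probability at time t read through the nomogram.

    Covariates outside the fitted range are clipped to it with a warning
    (chart extrapolation is meaningless). ``t`` may be any non-negative time;
    the baseline is step-interpolated.
    """
    clipped = {}
    for p in spec.predictors:
        x = float(patient[p])
        lo, hi = spec.ranges[p]
        if x < lo or x > hi:
            warnings.warn(f"covariate {p}={x:g} outside fitted range [{lo:g}, {hi:g}]; "
                          "clipping", stacklevel=2)
            x = min(max(x, lo), hi)
        clipped[p] = x
    if t <= 0:
        return 1.0
    lp = spec.lp_from_points(spec.total_points(clipped))
    s0 = spec.baseline_at(t)
    return float(s0 ** np.exp(lp - spec.mean_lp))


def _censoring_km_left(survival: pd.DataFrame) -> pd.Series:
    """Kaplan-Meier estimate of the censoring survival function G."""
    kmf = KaplanMeierFitter()
    kmf.fit(survival["time"], 1 - survival["event"])
    return kmf.survival_function_.iloc[:, 0]


def _left_limit(sf: pd.Series, t: np.ndarray) -> np.ndarray:
    """G(t-): value of the step function just before each t."""
    times = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)
    idx = np.searchsorted(times, t, side="left") - 1
    out = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 1.0)
    return out


def time_dependent_auc(scores: pd.Series, survival: pd.DataFrame, t: float) -> TimeROC:
    """Cumulative/dynamic time-dependent AUC at horizon t with IPCW weights.

    Cases (event by t) are weighted 1/G(T-) where G is the Kaplan-Meier
    censoring survival estimate; controls are patients with follow-up past t
    (their common weight cancels). Ties in score count 1/2. Returns NaN AUC
    when there is no case or no control at t.
    """
    df = pd.concat([scores.rename("score"), survival[["time", "event"]]],
                   axis=1).dropna()
    case = (df["time"].to_numpy() <= t) & (df["event"].to_numpy() == 1)
    control = df["time"].to_numpy() > t
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0 or n_controls == 0:
        logger.warning("time_dependent_auc: no %s at t=%g",
                       "cases" if n_cases == 0 else "controls", t)
        return TimeROC(float(t), float("nan"), n_cases, n_controls)
    G = _censoring_km_left(df)
    w = 1.0 / np.clip(_left_limit(G, df["time"].to_numpy()[case]), 1e-12, None)
    s_case = df["score"].to_numpy()[case]
    s_ctrl = df["score"].to_numpy()[control]
    greater = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    ties = (s_case[:, None] == s_ctrl[None, :]).astype(float)
    num = float((w[:, None] * (greater + 0.5 * ties)).sum())
    den = float(w.sum() * n_controls)
    return TimeROC(float(t), num / den, n_cases, n_controls)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop perfectly collinear columns, keeping the first by input order."""
    keep: list[str] = []
    arr = np.column_stack([np.ones(len(X))])
    for c in X.columns:
        cand = np.column_stack([arr, X[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(arr):
            keep.append(c)
            arr = cand
        else:
            logger.warning("stepwise_select: dropping collinear covariate %r", c)
    return X[keep]


def stepwise_select(X: pd.DataFrame, survival: pd.DataFrame,
                    alpha_enter: float = 0.05,
                    direction: str = "backward") -> CoxFit:
    """Stepwise multivariable Cox selection by Wald p-value.

    Backward (default): start from all candidates, repeatedly drop the
    least significant predictor until every retained one has p < alpha.
    Forward: greedily add the predictor with the smallest Wald p in the
    enlarged model while it stays below alpha. Deterministic given the data;
    perfectly collinear duplicates are removed first (first-by-order wins).
    If everything is eliminated the returned fit is flagged non-converged
    with no covariates.
    """
    X = _drop_collinear(X.reindex(survival.index))
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    empty = CoxFit(pd.DataFrame(columns=["beta", "hr", "ci_low", "ci_high", "p"]),
                   pd.Series(dtype=float), float("nan"), False,
                   len(survival), int(survival["event"].sum()))
    if direction == "backward":
        current = list(X.columns)
        while current:
            fit = cox_multivariable(X[current], survival)
            if not fit.converged:
                # drop the last covariate and retry; keeps selection deterministic
                current = current[:-1]
                continue
            p = fit.summary["p"]
            worst = p.idxmax()
            if float(p.max()) < alpha_enter:
                return fit
            current.remove(worst)
        logger.warning("stepwise_select: all candidates eliminated")
        return empty
    # forward
    current: list[str] = []
    remaining = list(X.columns)
    best_fit = None
    while remaining:
        trials = []
        for c in remaining:
            fit = cox_multivariable(X[current + [c]], survival)
            if fit.converged:
                trials.append((float(fit.summary["p"][c]), c, fit))
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], X.columns.get_loc(t[1])))
        p, c, fit = trials[0]
        if p >= alpha_enter:
            break
        current.append(c)
        remaining.remove(c)
        best_fit = fit
    if best_fit is None:
        logger.warning("stepwise_select: no candidate entered")
        return empty
    return best_fit
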