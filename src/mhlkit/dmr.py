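"""Differential methylation screening across disease states.

Blocks are first stratified by their mean MHL in localized disease: blocks
with localized mean MHL <= 0.05 ("low" stratum) are candidate tumor-derived
markers — localized patients shed almost no ctDNA, so methylation already
present there likely comes from non-tumor cells. The complementary "high"
stratum feeds the non-tumor-derived side analysis. Within each stratum every
block is tested between successive disease states (localized vs mHSPC and
mHSPC vs mCRPC) with two-sided Welch's unequal-variance t-tests at raw
p < 0.05; the intersection of the two significant sets is the differentially
methylated region (DMR) call set. No multiple-testing correction gates the
screen — a Benjamini-Hochberg q-value column is reported for reference only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratifiedMHBSets",
    "WelchResult",
    "stratify_by_localized",
    "welch_test",
    "run_dmr_screen",
    "DMRScreen",
]

logger = logging.getLogger(__name__)

STATES = ("localized", "mhspc", "mcrpc")
COMPARISONS = (("localized", "mhspc"), ("mhspc", "mcrpc"))


@dataclass(frozen=True)
class StratifiedMHBSets:
    """Partition of analyzed MHBs by localized-state mean MHL."""

    low_localized: tuple[str, ...]
    high_localized: tuple[str, ...]
    threshold: float = 0.05


class WelchResult(NamedTuple):
    t_stat: float
    p_value: float
    df: float


def stratify_by_localized(values: pd.DataFrame, states: pd.Series,
                          threshold: float = 0.05) -> StratifiedMHBSets:
    """Split MHB columns by mean MHL over localized samples vs the threshold.

    Boundary blocks (mean exactly at the threshold) go to the low stratum.
    """
    loc = states.index[states == "localized"]
    if len(loc) == 0:
        raise ValueError("localized group is empty")
    means = values.loc[loc].mean(axis=0)
    low = tuple(c for c in values.columns if means[c] <= threshold)
    high = tuple(c for c in values.columns if means[c] > threshold)
    return StratifiedMHBSets(low, high, threshold)


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's unequal-variance t-test.

    Degenerate cases follow the conventions: both groups with zero variance
    and equal means give t = 0, p = 1; zero variance with unequal means gives
    an infinite statistic and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, 1.0, float(len(a) + len(b) - 2))
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(float(t), 0.0, float(len(a) + len(b) - 2))
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue), float(res.df))


def _bh_q(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


@dataclass
class DMRScreen:
    """Output of the differential screen.

    ``table`` holds one row per (stratum, comparison, MHB) with the Welch
    statistic, raw p, reference q, the mean difference (later minus earlier
    state) and volcano coordinates; ``intersection`` maps stratum name to the
    sorted MHB ids significant in *both* comparisons.
    """

    table: pd.DataFrame
    intersection: dict[str, list[str]]
    significant: dict[tuple[str, str], list[str]]
    alpha: float


def run_dmr_screen(values: pd.DataFrame, states: pd.Series,
                   strata: StratifiedMHBSets, alpha: float = 0.05) -> DMRScreen:
    """Welch screen of every MHB between successive disease states.

    ``values`` must be the imputed MHL matrix (samples x MHBs); ``states``
    maps sample id to one of localized / mhspc / mcrpc. Per stratum and per
    comparison each MHB gets a two-sided Welch test; the DMR call set of a
    stratum is the intersection of the two comparisons' significant sets.
    """
    states = states.reindex(values.index)
    groups = {s: values.loc[states.index[states == s]] for s in STATES}
    rows = []
    significant: dict[tuple[str, str], list[str]] = {}
    for stratum, ids in (("low_localized", strata.low_localized),
                         ("high_localized", strata.high_localized)):
        ids = [c for c in ids if c in values.columns]
        for earlier, later in COMPARISONS:
            comp = f"{earlier}_vs_{later}"
            if not ids:
                significant[(stratum, comp)] = []
                continue
            A = groups[earlier][ids].to_numpy()
            B = groups[later][ids].to_numpy()
            res = stats.ttest_ind(B, A, axis=0, equal_var=False, nan_policy="omit")
            t = np.asarray(res.statistic, dtype=float)
            p = np.asarray(res.pvalue, dtype=float)
            mean_diff = np.nanmean(B, axis=0) - np.nanmean(A, axis=0)
            # degenerate columns (zero variance in both groups) -> convention
            degenerate = ~np.isfinite(p)
            equal = degenerate & (np.abs(mean_diff) < 1e-300)
            p[equal], t[equal] = 1.0, 0.0
            shifted = degenerate & ~equal
            p[shifted] = 0.0
            t[shifted] = np.where(mean_diff[shifted] > 0, np.inf, -np.inf)
            q = _bh_q(p)
            sig = p < alpha
            significant[(stratum, comp)] = [i for i, s in zip(ids, sig) if s]
            with np.errstate(divide="ignore"):
                neg_log10_p = -np.log10(np.clip(p, 1e-300, None))
            rows.append(pd.DataFrame({
                "mhb_id": ids, "stratum": stratum, "comparison": comp,
                "mean_diff": mean_diff, "t_stat": t, "p_value": p,
                "q_value": q, "significant": sig, "neg_log10_p": neg_log10_p,
            }))
    table = (pd.concat(rows, ignore_index=True) if rows else
             pd.DataFrame(columns=["mhb_id", "stratum", "comparison", "mean_diff",
                                   "t_stat", "p_value", "q_value", "significant",
                                   "neg_log10_p"]))
    intersection = {}
    for stratum in ("low_localized", "high_localized"):
        sets = [set(significant.get((stratum, f"{a}_vs_{b}"), []))
                for a, b in COMPARISONS]
        intersection[stratum] = sorted(set.intersection(*sets)) if sets else []
    for stratum, ids in intersection.items():
        logger.info("dmr screen: %s stratum -> %d common DMRs", stratum, len(ids))
    return DMRScreen(table, intersection, significant, alpha)
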