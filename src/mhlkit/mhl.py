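"""Methylation haplotype load (MHL) and the cohort MHL matrix.

MHL summarizes consecutive CpG methylation on reads. For substring length
``i`` let P(MH_i) be the count-weighted fraction of length-``i`` CpG
substrings (over all reads restricted to the block) that are fully
methylated. Then

    MHL = sum_i i * P(MH_i) / sum_i i,      i = 1..min(10, longest pattern)

so longer consecutive runs of methylation are weighted more heavily and the
value lies in [0, 1]. Lengths with zero observed substrings are omitted from
both numerator and denominator rather than treated as P = 0, which would
deflate MHL in shallow samples. A sample with no read overlapping any member
CpG of a block has *missing* MHL — missing is distinct from zero throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .blocks import MHB
from .io import HaplotypeRecord, SampleHaplotypeSet, TargetRegion

__all__ = [
    "MHLMatrix",
    "mhl",
    "mhl_from_patterns",
    "build_matrix",
    "drop_high_missingness",
    "knn_impute",
]

logger = logging.getLogger(__name__)

MAX_LEN = 10


def mhl_from_patterns(patterns: Sequence[str], counts: Sequence[int] | None = None,
                      max_len: int = MAX_LEN) -> float:
    """MHL of a pool of binary patterns (already restricted to one block).

    Returns NaN (missing) for an empty pool. ``counts`` defaults to 1 per
    pattern; the value is invariant to rescaling all counts by a common
    factor.
    """
    if counts is None:
        counts = [1] * len(patterns)
    if len(patterns) != len(counts):
        raise ValueError("patterns and counts must have equal length")
    if not patterns:
        return float("nan")

    lengths = np.array([len(p) for p in patterns], dtype=np.int64)
    cnt = np.asarray(counts, dtype=np.int64)
    if (cnt < 1).any():
        raise ValueError("counts must be >= 1")
    L = int(min(max_len, lengths.max()))

    # runs of consecutive '1's, count-weighted
    run_len: list[int] = []
    run_w: list[int] = []
    for p, c in zip(patterns, cnt):
        r = 0
        for ch in p:
            if ch == "1":
                r += 1
            else:
                if r:
                    run_len.append(r)
                    run_w.append(c)
                r = 0
        if r:
            run_len.append(r)
            run_w.append(c)
    runs = np.array(run_len, dtype=np.int64)
    rw = np.array(run_w, dtype=np.int64)

    i = np.arange(1, L + 1)
    # total length-i substrings: sum over reads of count * max(0, len - i + 1)
    tot = (cnt[None, :] * np.clip(lengths[None, :] - i[:, None] + 1, 0, None)).sum(axis=1)
    if runs.size:
        met = (rw[None, :] * np.clip(runs[None, :] - i[:, None] + 1, 0, None)).sum(axis=1)
    else:
        met = np.zeros_like(tot)
    keep = tot > 0
    weights = i[keep].astype(np.float64)
    frac = met[keep] / tot[keep]
    return float((weights @ frac) / weights.sum())


def restrict_pattern(record: HaplotypeRecord, region: TargetRegion, block: MHB) -> str | None:
    """Sub-pattern of a read over the block's member CpGs (None if disjoint).

    Member CpGs are consecutive in the region map, so the restriction is a
    contiguous substring. Reads only partially overlapping the block still
    contribute their overlap — discarding them would bias MHL down at block
    edges.
    """
    pos_index = {p: i for i, p in enumerate(region.cpg_positions)}
    off = pos_index[record.start]
    read_lo, read_hi = off, off + record.n_cpgs
    blk_lo = pos_index[block.cpg_positions[0]]
    blk_hi = pos_index[block.cpg_positions[-1]] + 1
    lo, hi = max(read_lo, blk_lo), min(read_hi, blk_hi)
    if lo >= hi:
        return None
    return record.pattern[lo - off:hi - off]


def mhl(records: Iterable[HaplotypeRecord], region: TargetRegion, block: MHB,
        max_len: int = MAX_LEN) -> tuple[float, int]:
    """MHL of one sample over one block, with its informative read support.

    Returns ``(value, support)`` where support is the count-weighted number
    of reads overlapping at least one member CpG; the value is NaN when
    support is zero (missing, not zero).
    """
    patterns: list[str] = []
    counts: list[int] = []
    for rec in records:
        sub = restrict_pattern(rec, region, block)
        if sub is not None:
            patterns.append(sub)
            counts.append(rec.count)
    support = int(sum(counts))
    return mhl_from_patterns(patterns, counts, max_len=max_len), support


@dataclass
class MHLMatrix:
    """Samples x MHBs matrix of MHL values with explicit missingness.

    ``values`` holds MHL in [0, 1] with NaN for missing cells; ``support``
    holds the parallel informative read counts. A cell is missing iff its
    support is zero.
    """

    values: pd.DataFrame
    support: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mhb_ids(self) -> list[str]:
        return list(self.values.columns)

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def subset(self, mhb_ids: Sequence[str]) -> "MHLMatrix":
        return MHLMatrix(self.values[list(mhb_ids)].copy(),
                         self.support[list(mhb_ids)].copy())

    def to_tsv(self, values_path, support_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep="NA", float_format="%.10g")
        if support_path is not None:
            self.support.to_csv(support_path, sep="\t")


def build_matrix(samples: Sequence[SampleHaplotypeSet], blocks: Sequence[MHB],
                 regions: Mapping[str, TargetRegion] | Sequence[TargetRegion],
                 max_len: int = MAX_LEN) -> MHLMatrix:
    """One MHL evaluation per sample x block; deterministic given inputs."""
    if not isinstance(regions, Mapping):
        regions = {r.name: r for r in regions}
    sample_ids = [s.sample_id for s in samples]
    values = np.full((len(samples), len(blocks)), np.nan)
    support = np.zeros((len(samples), len(blocks)), dtype=np.int64)
    for bi, block in enumerate(blocks):
        region = regions[block.region_name]
        for si, s in enumerate(samples):
            recs = s.records.get(block.region_name)
            if not recs:
                continue
            v, sup = mhl(recs, region, block, max_len=max_len)
            values[si, bi] = v
            support[si, bi] = sup
    names = [b.name for b in blocks]
    return MHLMatrix(
        pd.DataFrame(values, index=sample_ids, columns=names),
        pd.DataFrame(support, index=sample_ids, columns=names),
    )


def drop_high_missingness(matrix: MHLMatrix, max_missing_frac: float = 0.8
                          ) -> tuple[MHLMatrix, list[str]]:
    """Remove MHB columns whose missing fraction strictly exceeds the bound."""
    frac = matrix.missing_fraction()
    removed = [c for c in matrix.mhb_ids if frac[c] > max_missing_frac]
    kept = [c for c in matrix.mhb_ids if frac[c] <= max_missing_frac]
    logger.info("drop_high_missingness: removed %d of %d columns",
                len(removed), len(matrix.mhb_ids))
    return matrix.subset(kept), removed


def knn_impute(matrix: MHLMatrix, k: int = 5) -> MHLMatrix:
    """Impute missing MHL cells from the k nearest samples.

    Distances are Euclidean over mutually observed, per-column standardized
    MHB values (mean/SD from observed cells only); each missing cell becomes
    the mean of the column's values among the k nearest samples with an
    observed value, then is clipped back to [0, 1]. When fewer than ``k``
    donors exist the available ones are used (sklearn semantics) and a
    warning is logged.
    """
    vals = matrix.values
    if not vals.isna().any().any():
        return MHLMatrix(vals.copy(), matrix.support.copy())
    if vals.isna().all(axis=0).any():
        raise ValueError("knn_impute requires every column to have at least one "
                         "observed value; apply drop_high_missingness first")
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0).replace(0.0, 1.0).fillna(1.0)
    z = (vals - mu) / sd
    min_donors = int(vals.notna().sum(axis=0).min())
    if min_donors < k:
        logger.warning("knn_impute: a column has only %d observed values (< k=%d); "
                       "using all available donors", min_donors, k)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    z_imp = imputer.fit_transform(z.to_numpy())
    filled = pd.DataFrame(z_imp, index=vals.index, columns=vals.columns) * sd + mu
    filled = filled.clip(0.0, 1.0)
    out = vals.copy()
    out[out.isna()] = filled
    return MHLMatrix(out, matrix.support.copy())
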