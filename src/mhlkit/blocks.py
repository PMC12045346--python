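"""Methylation haplotype block (MHB) discovery.

An MHB is a maximal run of >=3 consecutive CpG sites whose methylation states
are in linkage disequilibrium across pooled reads: every *adjacent* pair of
member CpGs must show squared correlation r2 above a cutoff with an
association p-value below a cutoff, supported by enough informative reads.
Discovery is cohort-wide — reads from all samples are pooled per region.

The adjacent-pair criterion (rather than all pairs within a block) makes
discovery linear in the number of CpGs and mirrors how methylation-haplotype
tools construct blocks in practice. A CpG that is monomorphic in the pool has
undefined r2 with its neighbours and therefore breaks any block through it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HaplotypeRecord, TargetRegion

__all__ = ["LDResult", "MHB", "pairwise_r2", "discover_mhbs", "filter_mhbs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class LDResult:
    """Pairwise linkage disequilibrium between two CpG sites.

    ``r2`` is NaN and ``defined`` False when either site is monomorphic over
    the covering reads (an undefined r2 always fails any cutoff).
    """

    site_a: int
    site_b: int
    r2: float
    p_value: float
    n_reads: int
    defined: bool


@dataclass(frozen=True, slots=True)
class MHB:
    """A discovered block of CpG sites in linkage disequilibrium.

    ``start``/``end`` span the first to last member CpG, half-open, so the
    block always lies wholly inside its parent region.
    """

    chrom: str
    start: int
    end: int
    name: str
    cpg_positions: tuple[int, ...]
    region_name: str
    region_class: str = "target"

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def pattern_matrix(records: Iterable[HaplotypeRecord], region: TargetRegion
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse records into a (distinct pattern x CpG) int8 matrix.

    Cells are 1 (methylated), 0 (unmethylated) or -1 (site not covered by the
    read); the parallel weight vector carries count-aggregated multiplicities.
    Records are aggregated by (offset, pattern) so pooled cohorts stay small.
    """
    pos_index = {p: i for i, p in enumerate(region.cpg_positions)}
    agg: dict[tuple[int, str], int] = {}
    for rec in records:
        off = pos_index.get(rec.start)
        if off is None:
            raise ValueError(
                f"record at {rec.chrom}:{rec.start} does not start on a mapped "
                f"CpG of region {region.name}"
            )
        key = (off, rec.pattern)
        agg[key] = agg.get(key, 0) + rec.count
    n = region.n_cpgs
    mat = np.full((len(agg), n), -1, dtype=np.int8)
    weights = np.empty(len(agg), dtype=np.int64)
    for row, ((off, pattern), count) in enumerate(sorted(agg.items())):
        bits = np.frombuffer(pattern.encode(), dtype=np.uint8) - ord("0")
        mat[row, off:off + len(bits)] = bits
        weights[row] = count
    return mat, weights


def _pair_ld(mat: np.ndarray, weights: np.ndarray, ia: int, ib: int,
             site_a: int, site_b: int) -> LDResult:
    cov = (mat[:, ia] >= 0) & (mat[:, ib] >= 0)
    a = mat[cov, ia].astype(np.float64)
    b = mat[cov, ib].astype(np.float64)
    w = weights[cov].astype(np.float64)
    n = float(w.sum())
    if n == 0:
        return LDResult(site_a, site_b, math.nan, math.nan, 0, False)
    pa = float(w @ a) / n
    pb = float(w @ b) / n
    denom = pa * (1.0 - pa) * pb * (1.0 - pb)
    if denom <= 0.0:  # monomorphic at one or both sites
        return LDResult(site_a, site_b, math.nan, math.nan, int(n), False)
    p11 = float(w @ (a * b)) / n
    r2 = (p11 - pa * pb) ** 2 / denom
    r2 = min(r2, 1.0)
    p_value = float(stats.chi2.sf(n * r2, df=1))
    return LDResult(site_a, site_b, r2, p_value, int(n), True)


def pairwise_r2(records: Iterable[HaplotypeRecord], region: TargetRegion,
                site_a: int, site_b: int) -> LDResult:
    """LD between two CpG sites of a region over the covering reads.

    Builds the count-weighted 2x2 table of methylation states at the two
    sites and returns r2 = (p11 - pa*pb)^2 / (pa(1-pa) pb(1-pb)) with a 1-df
    chi-square p-value on n * r2. Symmetric in its sites and invariant to
    flipping methylated/unmethylated at both sites simultaneously.
    """
    for s in (site_a, site_b):
        if s not in region.cpg_positions:
            raise ValueError(f"site {s} is not in the CpG map of region {region.name}")
    mat, weights = pattern_matrix(records, region)
    ia = region.cpg_positions.index(site_a)
    ib = region.cpg_positions.index(site_b)
    return _pair_ld(mat, weights, ia, ib, site_a, site_b)


def discover_mhbs(records: Iterable[HaplotypeRecord], region: TargetRegion,
                  r2_cutoff: float = 0.3, core_window: int = 3,
                  p_cutoff: float = 0.05, min_pair_reads: int = 10) -> list[MHB]:
    """Find methylation haplotype blocks in one region from pooled reads.

    Scans the region's CpG sites in order; a block is a maximal run of
    consecutive CpGs in which every adjacent pair has defined r2 > r2_cutoff,
    p < p_cutoff and at least ``min_pair_reads`` informative reads. Runs
    shorter than ``core_window`` CpGs are discarded. Output blocks are
    disjoint, sorted, and invariant to the order in which samples were pooled.
    """
    if region.n_cpgs < core_window:
        logger.info("region %s has %d mapped CpGs (<%d); no blocks",
                    region.name, region.n_cpgs, core_window)
        return []
    mat, weights = pattern_matrix(records, region)
    pos = region.cpg_positions
    passing = np.zeros(region.n_cpgs - 1, dtype=bool)
    for j in range(region.n_cpgs - 1):
        ld = _pair_ld(mat, weights, j, j + 1, pos[j], pos[j + 1])
        passing[j] = (ld.defined and ld.n_reads >= min_pair_reads
                      and ld.r2 > r2_cutoff and ld.p_value < p_cutoff)
    blocks: list[MHB] = []
    j = 0
    while j < len(passing):
        if not passing[j]:
            j += 1
            continue
        k = j
        while k < len(passing) and passing[k]:
            k += 1
        member = pos[j:k + 1]  # run of pairs [j, k) covers CpGs j..k
        if len(member) >= core_window:
            blocks.append(MHB(
                chrom=region.chrom, start=member[0], end=member[-1] + 1,
                name=f"{region.name}:{len(blocks)}",
                cpg_positions=tuple(member),
                region_name=region.name, region_class=region.region_class,
            ))
        j = k + 1
    return blocks


def filter_mhbs(blocks: Sequence[MHB], read_support: pd.DataFrame,
                min_cpgs: int = 3, min_median_reads: int = 50) -> list[MHB]:
    """Retain blocks with >= ``min_cpgs`` CpGs and median read support
    strictly greater than ``min_median_reads`` across samples.

    ``read_support`` is a samples x block-name matrix of count-weighted reads
    overlapping each block (see :func:`mhlkit.mhl.build_matrix`). Blocks in
    control regions are *kept* here (they feed control reporting); excluding
    them from differential analysis is the caller's concern.
    """
    kept: list[MHB] = []
    for b in blocks:
        if b.n_cpgs < min_cpgs:
            continue
        if b.name not in read_support.columns:
            continue
        if float(read_support[b.name].median()) <= min_median_reads:
            continue
        kept.append(b)
    logger.info("filter_mhbs: kept %d of %d blocks", len(kept), len(blocks))
    return kept


def blocks_to_bed(blocks: Sequence[MHB], bed_path, sidecar_path=None) -> None:
    """Write blocks as BED4 plus an optional TSV sidecar with member CpGs."""
    with open(bed_path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("name\tregion\tregion_class\tn_cpgs\tcpg_positions\n")
            for b in blocks:
                fh.write(f"{b.name}\t{b.region_name}\t{b.region_class}\t"
                         f"{b.n_cpgs}\t{','.join(map(str, b.cpg_positions))}\n")
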