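"""Synthetic plasma-cfDNA methylation cohorts.

Generates read-level methylation haplotypes, target-region definitions and a
clinical table with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without patient data.

The generative model, per patient and target region:

* sequencing depth ~ negative binomial around ``mean_depth``;
* each read is tumor-derived with probability equal to the patient's ctDNA
  fraction — but only in the planted differentially-methylated (DMR)
  regions; elsewhere every read is background;
* reads follow a two-component epiallele model: a read is a *methylated*
  epiallele (per-CpG rate ``epiallele_high_meth``) with probability
  ``tumor_meth_prob`` for tumor reads and ``background_meth_prob`` for
  background reads, otherwise an unmethylated epiallele (rate
  ``epiallele_low_meth``). Given its component, the read draws one
  propensity pi ~ Beta(c*p, c*(1-p)) with concentration c (``coherence``)
  and methylates each covered CpG independently with probability pi. The
  shared per-read component creates runs of methylated CpGs and CpG-CpG
  linkage disequilibrium — the haplotype-level coherence that block
  discovery and the MHL statistic are designed to exploit; i.i.d. per-CpG
  flips would understate it;
* a random subset of regions (``high_background_frac``) gets an additive
  shift of the methylated-epiallele probability, applied identically to
  tumor and background reads: these regions carry constitutively methylated
  (non-tumor-derived) signal and populate the high-localized stratum of the
  differential screen. Because the shift is common to both read sources,
  setting ``tumor_meth_prob == background_meth_prob`` makes DMR regions an
  exact null across disease states;
* positive-control regions methylate all reads at >95% per CpG regardless of
  disease state; negative controls at <0.5%;
* ctDNA fraction is uniform on (0, 1%) in localized disease, intermediate in
  mHSPC, and wide in mCRPC with a configurable sub-1% mass (default mass
  17/49, matching the fraction of patients the correlation screen excludes);
* mCRPC survival is Weibull with log-hazard linear in the true risk
  (``hazard_coefficients`` on ctDNA fraction and expected DMR methylation),
  censored administratively at ``censor_horizon_months`` plus uniform early
  dropout; PSA/LDH/ALP/cfDNA are log-normal and positively correlated with
  ctDNA fraction, hemoglobin and albumin weakly negatively.

Ground truth (true fractions, planted DMR flags, true linear risk) is
emitted alongside the data and is never consumed by the pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (HaplotypeRecord, SampleHaplotypeSet, TargetRegion,
                 write_haplotypes, write_regions)

__all__ = ["CohortConfig", "GroundTruth", "Cohort", "default_config", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; a single seed fixes every draw."""

    # cohort sizes (localized / mHSPC / mCRPC)
    n_localized: int = 19
    n_mhspc: int = 28
    n_mcrpc: int = 49
    # region panel
    n_target_regions: int = 366
    n_dmr_regions: int = 250
    n_pos_control: int = 29
    n_neg_control: int = 42
    cpgs_per_region: int = 10
    # read generation
    mean_depth: float = 96.0
    depth_dispersion: float = 8.0       # NB size parameter
    tumor_meth_prob: float = 0.90       # methylated-epiallele prob., tumor reads
    background_meth_prob: float = 0.02  # methylated-epiallele prob., background
    epiallele_high_meth: float = 0.95   # per-CpG rate of a methylated epiallele
    epiallele_low_meth: float = 0.005   # per-CpG rate of an unmethylated one
    high_background_frac: float = 0.2   # regions with constitutive methylation
    high_background_shift: tuple[float, float] = (0.04, 0.35)
    pos_control_meth: float = 0.98
    neg_control_meth: float = 0.003
    coherence: float = 15.0             # Beta concentration of per-read propensity
    subwindow_prob: float = 0.3         # fraction of reads covering a sub-window
    min_read_cpgs: int = 3
    # ctDNA fractions
    mcrpc_low_fraction_mass: float = 17 / 49
    mcrpc_max_fraction: float = 0.80
    # survival (mCRPC only)
    hazard_coefficients: tuple[float, float] = (3.0, 2.0)  # (fraction, DMR methylation)
    weibull_shape: float = 1.3
    baseline_median_months: float = 28.0
    censor_horizon_months: float = 47.0
    dropout_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.tumor_meth_prob, self.background_meth_prob,
                 self.epiallele_high_meth, self.epiallele_low_meth,
                 self.high_background_frac,
                 self.pos_control_meth, self.neg_control_meth,
                 self.subwindow_prob, self.mcrpc_low_fraction_mass,
                 self.dropout_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_dmr_regions > self.n_target_regions:
            raise ValueError("n_dmr_regions must be <= n_target_regions")
        if min(self.n_localized, self.n_mhspc, self.n_mcrpc) <= 0:
            raise ValueError("degenerate config: every cohort must be non-empty")
        if self.n_target_regions + self.n_pos_control + self.n_neg_control <= 0:
            raise ValueError("degenerate config: no regions")


def default_config(**overrides) -> CohortConfig:
    """The default stated world; keyword overrides for scaled-down variants."""
    return dataclasses.replace(CohortConfig(), **overrides)


@dataclass
class GroundTruth:
    """Planted truth, emitted alongside the data, never read by the pipeline."""

    patients: pd.DataFrame   # sample_id-indexed: state, true_fraction, true_risk
    regions: pd.DataFrame    # region-indexed: is_dmr

    def write(self, patients_path, regions_path) -> None:
        self.patients.to_csv(patients_path)
        self.regions.to_csv(regions_path)


@dataclass
class Cohort:
    config: CohortConfig
    regions: list[TargetRegion]
    samples: list[SampleHaplotypeSet]
    clinical: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit the on-disk bundle (regions BED + CpG map, per-sample mHap
        files, clinical CSV, ground-truth CSVs kept clearly separate)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_regions(self.regions, out / "regions.bed", out / "cpg_map.tsv")
        hap_dir = out / "haplotypes"
        hap_dir.mkdir(exist_ok=True)
        for s in self.samples:
            write_haplotypes(s, hap_dir / f"{s.sample_id}.mhap.tsv")
        self.clinical.to_csv(out / "clinical.csv")
        self.ground_truth.write(out / "ground_truth_patients.csv",
                                out / "ground_truth_regions.csv")


def _make_regions(cfg: CohortConfig, rng: np.random.Generator
                  ) -> tuple[list[TargetRegion], np.ndarray]:
    """Region panel with per-region CpG maps; returns (regions, is_dmr)."""
    n_total = cfg.n_target_regions + cfg.n_pos_control + cfg.n_neg_control
    classes = (["target"] * cfg.n_target_regions
               + ["positive_control"] * cfg.n_pos_control
               + ["negative_control"] * cfg.n_neg_control)
    order = rng.permutation(n_total)
    classes = [classes[i] for i in order]
    dmr_targets = set(rng.choice(cfg.n_target_regions, size=cfg.n_dmr_regions,
                                 replace=False).tolist())
    is_dmr = np.zeros(n_total, dtype=bool)
    ti = 0
    regions: list[TargetRegion] = []
    cursors: dict[str, int] = {}
    width = len(str(n_total))
    for i, cls in enumerate(classes):
        chrom = f"chr{(i % 22) + 1}"
        cursor = cursors.get(chrom, 100_000)
        gaps = rng.integers(2, 40, size=cfg.cpgs_per_region)
        positions = cursor + 10 + np.cumsum(gaps)
        start, end = cursor, int(positions[-1]) + 10
        cursors[chrom] = end + 10_000
        if cls == "target":
            if ti in dmr_targets:
                is_dmr[i] = True
            ti += 1
        regions.append(TargetRegion(
            chrom=chrom, start=start, end=end,
            name=f"REG{i + 1:0{width}d}", region_class=cls,
            cpg_positions=tuple(int(p) for p in positions),
        ))
    return regions, is_dmr


def _draw_fractions(cfg: CohortConfig, rng: np.random.Generator,
                    states: np.ndarray) -> np.ndarray:
    f = np.zeros(len(states))
    loc = states == "localized"
    f[loc] = rng.uniform(0.0, 0.01, size=loc.sum())
    mh = states == "mhspc"
    f[mh] = rng.uniform(0.01, 0.10, size=mh.sum())
    mc = states == "mcrpc"
    n_mc = int(mc.sum())
    low = rng.random(n_mc) < cfg.mcrpc_low_fraction_mass
    vals = np.where(
        low,
        rng.uniform(0.0, 0.01, size=n_mc),
        0.01 + rng.beta(1.3, 1.8, size=n_mc) * (cfg.mcrpc_max_fraction - 0.01),
    )
    f[mc] = vals
    return f


def _draw_survival(cfg: CohortConfig, rng: np.random.Generator,
                   risk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weibull event times under proportional hazards, administratively
    censored at the horizon with uniform early dropout."""
    k = cfg.weibull_shape
    scale0 = cfg.baseline_median_months / math.log(2.0) ** (1.0 / k)
    centered = risk - risk.mean()
    e = rng.exponential(1.0, size=len(risk))
    T = scale0 * (e / np.exp(centered)) ** (1.0 / k)
    C = np.full(len(risk), cfg.censor_horizon_months)
    drop = rng.random(len(risk)) < cfg.dropout_prob
    C[drop] = rng.uniform(1.0, cfg.censor_horizon_months, size=int(drop.sum()))
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return np.maximum(time, 0.05), event


def _draw_biomarkers(rng: np.random.Generator, fractions: np.ndarray) -> pd.DataFrame:
    """Log-normal PSA/LDH/ALP/cfDNA loaded positively on log ctDNA fraction;
    albumin and hemoglobin weakly negative, on natural scales."""
    lf = np.log(fractions + 1e-3)
    z = (lf - lf.mean()) / (lf.std() if lf.std() > 0 else 1.0)
    n = len(fractions)
    e = lambda s: rng.normal(0.0, s, size=n)
    psa = np.exp(3.4 + 0.9 * z + e(0.6))
    ldh = np.exp(5.52 + 0.25 * z + e(0.15))
    alp = np.exp(4.60 + 0.50 * z + e(0.30))
    cfdna = np.exp(2.30 + 0.50 * z + e(0.50))
    albumin = np.clip(4.0 - 0.15 * z + e(0.30), 2.0, None)
    hemoglobin = np.clip(12.0 - 0.40 * z + e(1.00), 6.0, None)
    return pd.DataFrame({
        "psa": psa, "ldh": ldh, "alp": alp, "albumin": albumin,
        "hemoglobin": hemoglobin, "cfdna_ng_ml": cfdna,
    })


def _region_reads(cfg: CohortConfig, rng: np.random.Generator,
                  region: TargetRegion, is_dmr: bool, shift: float,
                  fractions: np.ndarray) -> list[dict[tuple[int, str], int]]:
    """Aggregated (offset, pattern) -> count per sample for one region."""
    n_samples = len(fractions)
    ncpg = region.n_cpgs
    size = cfg.depth_dispersion
    p_nb = size / (size + cfg.mean_depth)
    depths = rng.negative_binomial(size, p_nb, size=n_samples)
    N = int(depths.sum())
    out: list[dict[tuple[int, str], int]] = [dict() for _ in range(n_samples)]
    if N == 0 or ncpg == 0:
        return out
    sample_of = np.repeat(np.arange(n_samples), depths)

    min_len = min(cfg.min_read_cpgs, ncpg)
    offs = rng.integers(0, ncpg - min_len + 1, size=N)
    lens = min_len + (rng.random(N) * (ncpg - offs - min_len + 1)).astype(np.int64)
    full = rng.random(N) >= cfg.subwindow_prob
    offs[full] = 0
    lens[full] = ncpg

    if region.region_class == "positive_control":
        # near-universally methylated epialleles with a small partially
        # methylated minority: per-CpG mean ~0.977 (> 0.95) with enough
        # read-level variation to show CpG-CpG linkage disequilibrium
        methylated = rng.random(N) < cfg.pos_control_meth
        p_base = np.where(methylated, 0.995, 0.10)
    elif region.region_class == "negative_control":
        # rare methylated epialleles on a near-zero background: per-CpG
        # mean ~0.004 (< 0.005), still linked across neighbouring CpGs
        methylated = rng.random(N) < cfg.neg_control_meth
        p_base = np.where(methylated, 0.95, 0.001)
    else:
        # two-component epiallele model; the per-region shift is common to
        # tumor and background reads so it never mimics a disease-state effect
        if is_dmr:
            tumor = rng.random(N) < fractions[sample_of]
            weight = np.where(tumor, cfg.tumor_meth_prob, cfg.background_meth_prob)
        else:
            weight = np.full(N, cfg.background_meth_prob)
        weight = np.clip(weight + shift, 0.0, 1.0)
        methylated = rng.random(N) < weight
        p_base = np.where(methylated, cfg.epiallele_high_meth,
                          cfg.epiallele_low_meth)

    c = cfg.coherence
    pi = rng.beta(c * p_base, c * (1.0 - p_base))
    bits = (rng.random((N, ncpg)) < pi[:, None]).astype(np.uint8)
    text = (bits + ord("0")).tobytes().decode("ascii")

    for i in range(N):
        row = text[i * ncpg:(i + 1) * ncpg]
        o, l = int(offs[i]), int(lens[i])
        key = (o, row[o:o + l])
        d = out[int(sample_of[i])]
        d[key] = d.get(key, 0) + 1
    return out


def generate_cohort(config: CohortConfig | None = None,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate a full synthetic cohort (regions, haplotypes, clinical table,
    ground truth); byte-identical across runs with the same config.

    ``out_dir`` additionally writes the on-disk bundle in the formats of
    :mod:`mhlkit.io`.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    regions, is_dmr = _make_regions(cfg, rng)
    # constitutive (non-tumor-derived) methylation shift per region
    lo_s, hi_s = cfg.high_background_shift
    shifts = np.where(rng.random(len(regions)) < cfg.high_background_frac,
                      rng.uniform(lo_s, hi_s, size=len(regions)), 0.0)
    # planted DMRs model tumor-derived markers, which by construction have a
    # low non-tumor baseline; constitutive shifts go to non-DMR regions only
    shifts[is_dmr] = 0.0
    shifts[[r.region_class != "target" for r in regions]] = 0.0

    states = np.array(["localized"] * cfg.n_localized
                      + ["mhspc"] * cfg.n_mhspc
                      + ["mcrpc"] * cfg.n_mcrpc)
    sample_ids = ([f"L{i + 1:02d}" for i in range(cfg.n_localized)]
                  + [f"H{i + 1:02d}" for i in range(cfg.n_mhspc)]
                  + [f"C{i + 1:02d}" for i in range(cfg.n_mcrpc)])
    fractions = _draw_fractions(cfg, rng, states)

    # true linear risk: hazard coefficients on fraction and on the expected
    # per-CpG methylation of DMR regions implied by that fraction
    b_f, b_m = cfg.hazard_coefficients
    per_read = lambda w: (w * cfg.epiallele_high_meth
                          + (1.0 - w) * cfg.epiallele_low_meth)
    exp_meth = (fractions * per_read(cfg.tumor_meth_prob)
                + (1.0 - fractions) * per_read(cfg.background_meth_prob))
    risk = b_f * fractions + b_m * exp_meth

    mc = states == "mcrpc"
    time = np.full(len(states), np.nan)
    event = np.full(len(states), np.nan)
    t_mc, e_mc = _draw_survival(cfg, rng, risk[mc])
    time[mc], event[mc] = t_mc, e_mc

    biomarkers = _draw_biomarkers(rng, fractions)

    samples = [SampleHaplotypeSet(sample_id=sid) for sid in sample_ids]
    for ri, region in enumerate(regions):
        per_sample = _region_reads(cfg, rng, region, bool(is_dmr[ri]),
                                   float(shifts[ri]), fractions)
        pos = region.cpg_positions
        for si, agg in enumerate(per_sample):
            if not agg:
                continue
            recs = [
                HaplotypeRecord(
                    chrom=region.chrom, start=pos[off],
                    end=pos[off + len(pat) - 1] + 1,
                    pattern=pat, count=count, strand="+",
                )
                for (off, pat), count in sorted(agg.items())
            ]
            samples[si].records[region.name] = recs

    clinical = pd.DataFrame({
        "state": states, "time": time, "event": event,
        "ctdna_fraction": fractions,
    }, index=pd.Index(sample_ids, name="sample_id"))
    clinical = pd.concat([clinical, biomarkers.set_index(clinical.index)], axis=1)

    gt_patients = pd.DataFrame({
        "state": states, "true_fraction": fractions, "true_risk": risk,
    }, index=pd.Index(sample_ids, name="sample_id"))
    gt_regions = pd.DataFrame(
        {"is_dmr": is_dmr},
        index=pd.Index([r.name for r in regions], name="region"),
    )
    cohort = Cohort(cfg, regions, samples, clinical,
                    GroundTruth(gt_patients, gt_regions))
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
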