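# mhlkit

Read-level cfDNA methylation analysis for prognostication in metastatic
prostate cancer: methylation haplotype blocks, methylation haplotype load,
differential screening across disease states, Cox composite risk scores, and
survival nomograms with time-dependent ROC evaluation — plus a seeded
synthetic-cohort generator so the whole pipeline is testable without any
patient data.

## The problem

Plasma cell-free DNA (cfDNA) carries fragments of tumor DNA (ctDNA) whose
methylation patterns are tumor-specific. In metastatic castration-resistant
prostate cancer (mCRPC), where validated prognostic biomarkers are scarce,
coherent hypermethylation on individual cfDNA fragments is a candidate
readout of tumor burden and biology. The analytical chain this package
implements works from *read-level methylation haplotypes* — the ordered
binary methylation pattern of the CpGs on one sequencing read — rather than
from per-CpG averages, because tumor-derived fragments methylate runs of
neighbouring CpGs together while background cfDNA does not.

## The statistics at the core

**Methylation haplotype blocks (MHBs).** Within each targeted region, reads
from all patients are pooled and adjacent CpG pairs are scored for linkage
disequilibrium, `r² = (p₁₁ − pₐ·p_b)² / (pₐ(1−pₐ)·p_b(1−p_b))` over the
count-weighted 2×2 table of methylation states, with a 1-df chi-square
p-value on `n·r²`. An MHB is a maximal run of ≥3 consecutive CpGs whose
every adjacent pair has r² > 0.3, p < 0.05 and enough informative reads.
Blocks are then filtered to ≥3 CpGs and median read support strictly
above 50 across samples.

**Methylation haplotype load (MHL).** For a sample's reads restricted to a
block, with `P(MHᵢ)` the count-weighted fraction of fully methylated
length-`i` CpG substrings,

    MHL = Σᵢ i · P(MHᵢ) / Σᵢ i ,   i = 1 … min(10, longest pattern)

MHL ∈ [0, 1] weights long consecutive methylation runs more heavily; a
sample with no informative read has *missing* MHL (never zero). MHB columns
with >80% missing values are dropped and the rest KNN-imputed (k = 5).

**Differential screen.** MHBs with localized-state mean MHL ≤ 0.05 are
candidate tumor-derived markers (localized disease sheds <1% ctDNA; higher
baseline signal is non-tumor-derived). Each block gets two-sided Welch
t-tests for localized vs mHSPC and mHSPC vs mCRPC; the DMR call set is the
intersection of the two significant sets at raw p < 0.05 (a
Benjamini–Hochberg q-value column is reported but never gates the calls).

**Risk modelling.** Univariate Cox proportional-hazards fits (Efron ties,
Breslow baseline) screen the DMRs against mCRPC overall survival; the top 20
significant DMRs, collapsed to one block per gene region keeping the highest
hazard ratio, form a panel with composite score `C = Σ βᵢ·Mᵢ`. A
multivariable Cox model on `C`, predicted ctDNA fraction (raw 0–1 scale) and
log₂ clinical biomarkers yields a risk score `R = Σ βⱼ·xⱼ`; the median split
of `R` (strictly greater → high-risk) is compared by Kaplan–Meier curves and
the log-rank test. MHBs are separately screened for Pearson correlation with
predicted ctDNA fraction (r > 0.5, p < 0.05, patients above 1% fraction
only, columns with >50% observed values).

**Nomogram.** Backward-stepwise Cox selection picks independent predictors;
each is mapped affinely to points (the strongest predictor spans 0–100), so
total points are a bijection of the linear predictor and chart-read survival
at 6/12/24 months equals the Cox prediction `S₀(t)^exp(lp − mean lp)`
exactly. Performance is the IPCW (Kaplan–Meier censoring weights)
cumulative/dynamic time-dependent ROC AUC.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/07_full_pipeline.py` (a 96-patient synthetic cohort with a
reduced 72-region panel, seed 1) prints, among other counts:

```
  discovered_mhbs: 73
  filtered_mhbs: 73
  low_localized: 57
  intersection_low: 41
  panel_size: 20
ground-truth recovery:
  DMR precision 1.00, recall 1.00
  correlation-flagged blocks in planted regions: 1.00
  Cox beta on true risk: 1.13 (1.0 = hazards generated exactly as modelled)
  KM medians: high-risk 13.4 months, low-risk not reached, log-rank p = 3.3e-05
```

Reading: 73 blocks were discovered and survived filtering, 57 sat in the
low-localized stratum, 41 passed both Welch screens, and the 20-block panel's
risk score split mCRPC patients into groups whose survival differs by years.
Because the cohort is synthetic, every call can be scored against the
planted truth — here the screen recovered exactly the planted DMR regions
and the Cox model on the true risk returned a coefficient near 1, as the
proportional-hazards construction implies.

## The acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default-scale synthetic cohort (19 localized / 28 mHSPC /
49 mCRPC patients; 366 target, 29 positive-control and 42 negative-control
regions at ~96× depth) from the seed, runs every pipeline stage end to end,
and prints the stage funnel plus the ground-truth recovery report before
writing the result JSON to `--out`. It takes about a minute on one CPU.
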