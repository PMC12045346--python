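# Methods

This note documents the models and conventions behind `mhlkit`: what each
stage assumes, which parameters matter, what the synthetic cohort does and
does not emulate, and the choices made where the design was genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention); a CpG position is
the C of the CpG dinucleotide on the forward strand. Haplotype files are
mHap-style TSV (`chrom, start, end, pattern, count, strand`); patterns are
assumed already oriented to forward-strand CpG order by the upstream
converter, so minus-strand records are never reverse-complemented. A record
is assigned to the target region containing its *first* CpG, and its
pattern length must equal the number of mapped CpG positions in
`[start, end)` — reads with uncalled CpGs inside a span cannot be
represented and are rejected with a line-level error. Unmapped records are
tallied, never silently dropped, so count-weighted read mass is conserved
through parsing.

## Block discovery

Blocks are discovered cohort-wide: reads of all samples are pooled per
region before LD is computed, so the block map is a property of the cohort,
not of a patient. The criterion is adjacent-pair LD — every neighbouring
CpG pair inside a block must pass — rather than all-pairs LD; this is how
methylation-haplotype block construction is usually implemented, and it
makes discovery linear in the number of CpGs. Parameters:

| parameter | default | meaning |
|---|---|---|
| `r2_cutoff` | 0.3 | minimum adjacent-pair squared correlation |
| `p_cutoff` | 0.05 | chi-square (1 df, `n·r²`) significance per pair |
| `core_window` | 3 | minimum CpGs per block |
| `min_pair_reads` | 10 | informative reads per pair; below this, r² is noise |
| `min_cpgs`, `min_median_reads` | 3, 50 | post-hoc block filters; the median rule is strict (`> 50`) |

A monomorphic site has undefined r² with its neighbours and therefore
breaks any block through it (undefined ⇒ criterion not met). The published
description of the block-discovery tool does not define its p-value or
core-window semantics precisely; the interpretation above (per-pair
significance filter; minimum block size) is this package's documented
reading, exposed in configuration rather than hard-coded.

## MHL conventions

Three conventions matter numerically:

* **Partial overlaps contribute.** A read overlapping a block in ≥1 member
  CpG contributes its restricted sub-pattern. Discarding edge reads would
  bias MHL downward at block boundaries.
* **Unobserved lengths are omitted.** Substring lengths `i` with zero
  observed substrings are left out of both the numerator and denominator of
  the weighted mean, rather than entered as `P(MHᵢ) = 0`. Treating them as
  zero would deflate MHL in shallow samples purely as a function of depth.
* **Missing ≠ zero.** A sample×block cell is missing exactly when no read
  informs the block (`read_support = 0`). Zero means "observed and
  unmethylated".

The length cap is 10: patterns longer than 10 CpGs contribute substrings of
length 1–10 only. The implementation (run-length counting) is verified
against an exhaustive substring-enumeration oracle to 1e-12 in the tests.

Missingness handling: block columns with >80% missing cells are removed
(strictly greater; a column at exactly 80% is kept), then remaining holes
are KNN-imputed with k = 5 — the method is named in the underlying
analysis, the neighbour count is not; 5 is the standard default and is
exposed in configuration. Distances are Euclidean over mutually observed,
per-column standardized values (scikit-learn's nan-Euclidean convention);
imputed values are clipped back to [0, 1].

## Differential screen

The localized-MHL stratification threshold is 0.05, with *boundary blocks
assigned to the low stratum* (≤ 0.05): the source wording is inconsistent
("less than" vs "≤"), and the inclusive reading keeps boundary blocks in
the tumor-derived analysis. Welch's unequal-variance t-test is used
everywhere with no pooled-variance fallback; degenerate cases follow fixed
conventions (both groups constant and equal → t = 0, p = 1; constant with
unequal means → p = 0). No multiple-testing correction gates the screen —
the call set is the intersection of two raw p < 0.05 screens, matching the
original analysis — but a Benjamini–Hochberg q-value column is reported for
users who want it. The high-localized stratum is carried through the same
machinery (it feeds the non-tumor-derived side analysis, e.g. a top-3
composite) rather than a separate code path.

## Survival modelling

Cox fits use lifelines with Efron tie handling and the Breslow baseline.
Panel selection ranks the intersection DMRs by their mHSPC-vs-mCRPC Welch
p-value (ascending) — the comparison that defines the transition into the
modelled disease state. The ranking key behind "top 20" is not specified by
the source analysis; this choice is configurable (`rank_comparison`).
Gene-level collapse keeps the highest hazard ratio per gene region, with
equal-HR ties broken to the leftmost genomic position for determinism.

Risk scores: clinical biomarkers (PSA ng/mL, LDH U/L, ALP U/L, albumin
g/dL, hemoglobin g/dL) enter Cox models log₂-transformed; predicted ctDNA
fraction enters on its raw 0–1 scale — per-unit hazard ratios on a raw
fraction are therefore numerically enormous with wide confidence intervals,
which is expected, not a defect. The median split labels scores *strictly
greater* than the median as high-risk (ties low), giving ⌊n/2⌋ high and
⌈n/2⌉ low patients.

The ctDNA-fraction correlation screen first excludes patients at ≤1%
predicted fraction (the predictor is unreliable there), requires >50%
observed values per block among the remaining patients, and flags blocks
with Pearson r > 0.5 and p < 0.05. The external fraction predictor itself
is out of scope: predicted fraction is a pipeline *input*.

## Nomogram and AUC

Point scales are exact affine maps: predictor `j` contributes
`100·βⱼ·(x − x_ref,j)/scale` points with `x_ref,j` the observed-range end
minimizing `βⱼ·x` and `scale = maxⱼ |βⱼ|·rangeⱼ`, so points are
non-negative and exactly one predictor spans 0–100. Probability lookups
invert the affine map; the 1-point tabulation exists only for rendering.
The baseline survival is the Breslow estimator evaluated by *step*
interpolation (off-grid, the value at the largest event time ≤ t); note
that lifelines linearly interpolates off-grid query times, so comparisons
are exact only on the baseline grid. Covariates outside the fitted range
are clipped with a warning — chart extrapolation is meaningless.

Stepwise selection is backward elimination on Wald p-values from the
univariate-significant candidate set (the source analysis says only
"stepwise"); forward selection is available via `direction="forward"`.
Perfectly collinear candidates are removed first, keeping the first by
input order.

The time-dependent AUC is the cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights from a Kaplan–Meier fit to
the censoring distribution (Uno-type); cases are weighted `1/G(T⁻)`, the
controls' common weight cancels, and score ties count ½. With no censoring
it reduces exactly to the rank-sum AUC. The estimator choice is a
documented decision — the source names only "time-dependent ROC".

## The synthetic cohort

The generator emulates the stated structure of the study cohort:
19/28/49 patients (localized/mHSPC/mCRPC), 366 target + 29 positive-control
+ 42 negative-control regions, ~96× mean depth (negative binomial,
dispersion 8), and an mCRPC predicted-fraction distribution calibrated so
~17/49 fall below 1%. Survival exists for mCRPC only, as in the study.

Reads follow a two-component epiallele model: each read is a *methylated
epiallele* (per-CpG rate 0.95) with probability 0.90 if tumor-derived and
0.02 if background, otherwise a near-zero epiallele (rate 0.005); given its
component the read draws one Beta-distributed propensity (concentration 15)
and methylates covered CpGs independently. The shared per-read component is
what creates runs of methylated CpGs and CpG–CpG LD — the haplotype-level
coherence both block discovery and MHL exploit; i.i.d. per-CpG flips would
understate it. A read is tumor-derived with probability equal to the
patient's ctDNA fraction, in planted DMR regions only. About 20% of
non-DMR target regions get a constitutive methylation shift (U(0.04, 0.35)
added to the epiallele weight of *both* read sources), populating the
high-localized stratum; because the shift is source-symmetric, setting the
tumor weight equal to the background weight yields an exact across-state
null. Positive controls are 98% methylated epialleles (per-CpG mean ≈0.977),
negative controls 0.3% (mean ≈0.004), so both control classes yield blocks
with MHL medians near 1 and 0 respectively.

Fraction distributions: localized U(0, 0.01); mHSPC U(0.01, 0.10) as the
intermediate state; mCRPC a 17/49 : 32/49 mixture of U(0, 0.01) and
0.01 + Beta(1.3, 1.8)·0.79. 250 of 366 target regions carry tumor signal —
the panel the study targeted was built from known prostate-cancer DMRs, and
it reported ~73% of blocks tracking ctDNA fraction and 720/955 blocks
shifting between mHSPC and mCRPC; a sparse planting would contradict that
structure. Survival is Weibull (shape 1.3, baseline median 28 months at the
mean risk) with log-hazard linear in the true risk
`3·fraction + 2·E[DMR methylation]`, administratively censored at 47 months
(the follow-up window) plus 15% uniform early dropout — yielding ≈0.65–0.70
event rates, near the reported 34/49. PSA/LDH/ALP/cfDNA are log-normal with
positive loadings on log fraction; hemoglobin and albumin have weak
negative loadings. All randomness flows from one seed through a single
generator; identical configs produce byte-identical output files.

**What the generator does not emulate** — and hence what a green test does
not establish: fragment-length and nucleosome-positioning signal, copy
number, per-region depth biases (GC, mappability), correlated missingness,
batch effects, non-proportional hazards, and any real biological identity
of the regions (names are synthetic). Green tests establish that the
*pipeline machinery* recovers planted structure under its own model
assumptions at realistic sample sizes — not that the markers would validate
clinically.

## Numerical and degenerate-input conventions

* r² is clamped to [0, 1] against floating-point overshoot; monomorphic
  sites are flagged undefined rather than zero.
* Cox fits that fail to converge (monotone likelihood, separation) come
  back flagged and are excluded from panel selection with a warning, never
  silently dropped.
* A correlation screen with fewer than 3 eligible patients aborts with an
  explicit error.
* Groups with zero events report their KM median as "not reached" (NaN).
* Matrix columns, block names and panel order are sorted deterministically;
  two runs of the pipeline with the same config and seed are byte-identical
  (the config echo in artifacts nulls the output directory so the location
  itself does not break identity).

## Known limitations

* Block discovery uses adjacent-pair LD only; long-range within-block
  structure is not re-checked.
* The KNN imputer inherits scikit-learn's nan-Euclidean scaling, which can
  rank neighbours slightly differently from a plain mutual-Euclidean
  distance when missingness patterns differ.
* The nomogram's AUC is computed on the fitting data (apparent
  performance); no internal validation/bootstrap is provided.
* No competing risks, time-varying covariates, or proportional-hazards
  diagnostics beyond fit warnings.
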