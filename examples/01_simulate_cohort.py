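"""Generate a synthetic plasma-cfDNA methylation cohort and look at it.

The generator emulates a three-state prostate-cancer cohort (localized,
mHSPC, mCRPC): read-level methylation haplotypes over a targeted region
panel, a clinical table with survival and biomarkers, and a separate
ground-truth file that the analysis never reads.
"""

from mhlkit.simulate import default_config, generate_cohort

# a reduced region panel keeps this demo fast; patient structure, depth and
# effect sizes are the package defaults
cfg = default_config(seed=7, n_target_regions=40, n_dmr_regions=27,
                     n_pos_control=4, n_neg_control=4)
cohort = generate_cohort(cfg)

print(f"{len(cohort.samples)} samples, {len(cohort.regions)} regions")
print("\nPatients per state:")
print(cohort.clinical["state"].value_counts().to_string())

print("\nPredicted ctDNA fraction by state (median):")
print(cohort.clinical.groupby("state")["ctdna_fraction"].median().round(4).to_string())
# localized sheds <1% ctDNA, mHSPC is intermediate, mCRPC wide -- the
# gradient every downstream stage relies on

mc = cohort.clinical[cohort.clinical.state == "mcrpc"]
print(f"\nmCRPC survival: {int(mc.event.sum())}/{len(mc)} deaths, "
      f"median follow-up {mc.time.median():.1f} months")

one = cohort.samples[0]
region = cohort.regions[0]
recs = one.records.get(region.name, [])[:3]
print(f"\nFirst reads of {one.sample_id} in {region.name} "
      f"({region.region_class}):")
for r in recs:
    print(f"  {r.chrom}:{r.start}-{r.end}  pattern={r.pattern}  count={r.count}")
# each pattern is one read's methylation haplotype: 1 = methylated CpG
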