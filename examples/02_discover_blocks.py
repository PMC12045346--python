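"""Discover methylation haplotype blocks (MHBs) from pooled reads.

A block is a maximal run of >=3 consecutive CpGs whose adjacent pairs show
linkage disequilibrium (r^2 > 0.3, p < 0.05) across reads pooled from the
whole cohort. Filtering then keeps blocks with >=3 CpGs and median read
support strictly above 50 across samples.
"""

from mhlkit.blocks import discover_mhbs, filter_mhbs, pairwise_r2
from mhlkit.mhl import build_matrix
from mhlkit.simulate import default_config, generate_cohort

cfg = default_config(seed=7, n_target_regions=12, n_dmr_regions=8,
                     n_pos_control=2, n_neg_control=2)
cohort = generate_cohort(cfg)

# pool every sample's reads per region -- block discovery is cohort-wide
pooled = {}
for s in cohort.samples:
    for name, recs in s.records.items():
        pooled.setdefault(name, []).extend(recs)

region = cohort.regions[0]
a, b = region.cpg_positions[0], region.cpg_positions[1]
ld = pairwise_r2(pooled[region.name], region, a, b)
print(f"adjacent pair {a}/{b} in {region.name}: "
      f"r2={ld.r2:.3f} p={ld.p_value:.2e} over {ld.n_reads} reads")
# r2 near 1 means the two CpGs are methylated on the same reads

blocks = []
for region in cohort.regions:
    blocks += discover_mhbs(pooled[region.name], region)
print(f"\ndiscovered {len(blocks)} blocks across {len(cohort.regions)} regions")

matrix = build_matrix(cohort.samples, blocks, cohort.regions)
kept = filter_mhbs(blocks, matrix.support)
print(f"after CpG-count and median-read filters: {len(kept)} blocks")
for blk in kept[:5]:
    print(f"  {blk.name}  {blk.chrom}:{blk.start}-{blk.end}  "
          f"{blk.n_cpgs} CpGs  ({blk.region_class})")
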