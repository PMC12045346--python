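import numpy as np
import pytest

from mhlkit.blocks import MHB
from mhlkit.io import HaplotypeRecord, TargetRegion
from mhlkit.pipeline import PipelineConfig, run_pipeline
from mhlkit.simulate import default_config, generate_cohort


@pytest.fixture
def toy_region():
    """Six-CpG region on chr17 used by the hand-built record tests."""
    return TargetRegion(
        chrom="chr17", start=2056970, end=2057060, name="TOY",
        region_class="target",
        cpg_positions=(2056975, 2056990, 2057010, 2057025, 2057040, 2057050),
    )


def make_records(region, specs):
    """specs: iterable of (offset, pattern, count) relative to the CpG map."""
    out = []
    pos = region.cpg_positions
    for off, pattern, count in specs:
        out.append(HaplotypeRecord(
            chrom=region.chrom, start=pos[off],
            end=pos[off + len(pattern) - 1] + 1,
            pattern=pattern, count=count, strand="+",
        ))
    return out


def region_of(n_cpgs, name="R", start=1000, spacing=10, region_class="target"):
    positions = tuple(start + spacing * i for i in range(n_cpgs))
    return TargetRegion(chrom="chr1", start=start - 5, end=positions[-1] + 5,
                        name=name, region_class=region_class,
                        cpg_positions=positions)


def block_of(region, lo, hi, name=None):
    """MHB over CpG-map indices [lo, hi) of a region."""
    member = region.cpg_positions[lo:hi]
    return MHB(chrom=region.chrom, start=member[0], end=member[-1] + 1,
               name=name or f"{region.name}:0", cpg_positions=member,
               region_name=region.name, region_class=region.region_class)


# a scaled-down cohort: default statistical structure (patient counts, depth,
# fraction distributions, planted-DMR share) with fewer regions for speed
SMALL_COHORT_KW = dict(n_target_regions=24, n_dmr_regions=16,
                       n_pos_control=3, n_neg_control=3)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_config(seed=11, **SMALL_COHORT_KW))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_pipeline(PipelineConfig(), cohort=small_cohort)
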