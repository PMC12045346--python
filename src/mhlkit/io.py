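"""Read-level methylation haplotype I/O.

A methylation haplotype is the ordered binary methylation pattern of the CpG
sites covered by one sequencing read (1 = methylated, 0 = unmethylated). The
on-disk format is mHap-style tab-separated text with six columns::

    chrom  start  end  pattern  count  strand

Coordinates are 0-based half-open throughout (BED convention); a CpG position
refers to the C of the CpG dinucleotide on the forward strand, and ``pattern``
is ordered by genomic position. ``count`` aggregates identical reads.

Target regions are BED-like records carrying a name and a class label
(``target``, ``positive_control`` or ``negative_control``) plus an ordered map
of the CpG positions they contain.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HaplotypeRecord",
    "TargetRegion",
    "SampleHaplotypeSet",
    "HaplotypeParseError",
    "RegionError",
    "read_regions",
    "write_regions",
    "read_haplotypes",
    "write_haplotypes",
]

REGION_CLASSES = ("target", "positive_control", "negative_control")

_PATTERN_CHARS = frozenset("01")
_STRANDS = frozenset("+-*")


class HaplotypeParseError(ValueError):
    """A haplotype line could not be interpreted (carries line context)."""


class RegionError(ValueError):
    """A region definition violates the coordinate/class invariants."""


@dataclass(frozen=True, slots=True)
class HaplotypeRecord:
    """One read's binary methylation pattern over consecutive CpG sites.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based position of the first covered CpG.
    end : int
        Half-open end; the interval [start, end) contains exactly
        ``len(pattern)`` mapped CpG positions.
    pattern : str
        String over ``{0,1}``, one symbol per covered CpG, 1 = methylated.
    count : int
        Read multiplicity (>= 1).
    strand : str
        One of ``+``, ``-``, ``*``. Patterns are assumed already oriented to
        forward-strand CpG order by the upstream converter.
    """

    chrom: str
    start: int
    end: int
    pattern: str
    count: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if not self.pattern or not _PATTERN_CHARS.issuperset(self.pattern):
            raise HaplotypeParseError(
                f"pattern must be a non-empty string over {{0,1}}, got {self.pattern!r}"
            )
        if self.count < 1:
            raise HaplotypeParseError(f"count must be >= 1, got {self.count}")
        if self.start >= self.end:
            raise HaplotypeParseError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise HaplotypeParseError(f"strand must be one of + - *, got {self.strand!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True, slots=True)
class TargetRegion:
    """A capture target with its class label and ordered CpG position map."""

    chrom: str
    start: int
    end: int
    name: str
    region_class: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RegionError(f"{self.name}: start must be < end")
        if self.region_class not in REGION_CLASSES:
            raise RegionError(
                f"{self.name}: unknown region class {self.region_class!r}; "
                f"expected one of {REGION_CLASSES}"
            )
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise RegionError(f"{self.name}: CpG positions must be strictly increasing")
        if pos and (pos[0] < self.start or pos[-1] >= self.end):
            raise RegionError(
                f"{self.name}: CpG positions must lie within [{self.start}, {self.end})"
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class SampleHaplotypeSet:
    """All haplotype records of one sample, grouped by target region.

    Records that do not fall in any region are kept in ``unmapped`` (counted,
    never silently dropped); malformed input lines are collected in
    ``errors`` as ``(line_number, message)`` pairs.
    """

    sample_id: str
    records: dict[str, list[HaplotypeRecord]] = field(default_factory=dict)
    unmapped: list[HaplotypeRecord] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values()) + len(self.unmapped)

    @property
    def total_reads(self) -> int:
        """Count-weighted read mass (mapped + unmapped)."""
        mapped = sum(r.count for v in self.records.values() for r in v)
        return mapped + sum(r.count for r in self.unmapped)

    def all_records(self) -> Iterable[HaplotypeRecord]:
        for region in sorted(self.records):
            yield from self.records[region]
        yield from self.unmapped


class _RegionIndex:
    """Assigns a record to the region containing its first CpG."""

    def __init__(self, regions: Sequence[TargetRegion]):
        self.by_chrom: dict[str, tuple[list[int], list[TargetRegion]]] = {}
        for chrom in {r.chrom for r in regions}:
            rs = sorted((r for r in regions if r.chrom == chrom), key=lambda r: r.start)
            self.by_chrom[chrom] = ([r.start for r in rs], rs)

    def locate(self, chrom: str, pos: int) -> TargetRegion | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, rs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < rs[i].end:
            return rs[i]
        return None


def read_regions(path: str | Path, cpg_map_path: str | Path) -> list[TargetRegion]:
    """Load target regions (BED-like) together with their CpG position map.

    The BED-like file has columns chrom, start, end, name, class. The CpG map
    is either a two-column TSV of (chrom, position) — positions are assigned
    to regions by containment — or a JSON object mapping region name to a
    position list, in which case out-of-bounds positions are an error.

    Regions are returned sorted by (chrom, start); overlapping regions on the
    same chromosome are rejected.
    """
    path, cpg_map_path = Path(path), Path(cpg_map_path)
    raw: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise RegionError(f"{path}:{lineno}: expected >=5 columns, got {len(cols)}")
            chrom, start, end, name, cls = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4]
            raw.append((chrom, start, end, name, cls))

    if cpg_map_path.suffix == ".json":
        with open(cpg_map_path) as fh:
            per_region: Mapping[str, list[int]] = json.load(fh)
        pos_for = lambda chrom, start, end, name: sorted(per_region.get(name, []))
        strict_bounds = True
    else:
        by_chrom: dict[str, list[int]] = defaultdict(list)
        with open(cpg_map_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                c, p = line.split("\t")[:2]
                by_chrom[c].append(int(p))
        for c in by_chrom:
            by_chrom[c].sort()

        def pos_for(chrom: str, start: int, end: int, name: str) -> list[int]:
            arr = by_chrom.get(chrom, [])
            lo = bisect_right(arr, start - 1)
            hi = bisect_right(arr, end - 1)
            return arr[lo:hi]

        strict_bounds = False

    regions = []
    for chrom, start, end, name, cls in raw:
        positions = pos_for(chrom, start, end, name)
        if strict_bounds and positions and (positions[0] < start or positions[-1] >= end):
            raise RegionError(
                f"{name}: CpG map lists positions outside [{start}, {end})"
            )
        regions.append(TargetRegion(chrom, start, end, name, cls, tuple(positions)))

    regions.sort(key=lambda r: (r.chrom, r.start))
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise RegionError(f"overlapping regions {a.name} and {b.name} on {a.chrom}")
    return regions


def write_regions(regions: Sequence[TargetRegion], bed_path: str | Path,
                  cpg_map_path: str | Path) -> None:
    """Emit regions as BED5 plus a two-column (chrom, position) CpG map."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.region_class}\n")
    with open(cpg_map_path, "w") as fh:
        for r in regions:
            for p in r.cpg_positions:
                fh.write(f"{r.chrom}\t{p}\n")


def read_haplotypes(path: str | Path, regions: Sequence[TargetRegion],
                    sample_id: str | None = None, strict: bool = False) -> SampleHaplotypeSet:
    """Parse an mHap-style haplotype file and index records by target region.

    Each record is assigned to the region containing its *first* CpG; its
    pattern length is cross-checked against the number of mapped CpG
    positions in ``[start, end)``. Malformed lines are recorded in
    ``errors`` with their line number (or raised when ``strict``).
    """
    path = Path(path)
    if not regions:
        raise ValueError("regions must be non-empty")
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    index = _RegionIndex(regions)
    out = SampleHaplotypeSet(sample_id=sample_id)
    pos_index = {r.name: {p: i for i, p in enumerate(r.cpg_positions)} for r in regions}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                _record_error(out, lineno, f"expected 6 columns, got {len(cols)}", strict)
                continue
            try:
                rec = HaplotypeRecord(
                    chrom=cols[0], start=int(cols[1]), end=int(cols[2]),
                    pattern=cols[3], count=int(cols[4]), strand=cols[5],
                )
            except (ValueError, HaplotypeParseError) as exc:
                _record_error(out, lineno, str(exc), strict)
                continue
            region = index.locate(rec.chrom, rec.start)
            if region is None:
                out.unmapped.append(rec)
                continue
            # pattern length must equal the number of mapped CpGs in the span
            pmap = pos_index[region.name]
            if rec.start not in pmap:
                _record_error(
                    out, lineno,
                    f"start {rec.start} is not a mapped CpG in region {region.name}",
                    strict,
                )
                continue
            i0 = pmap[rec.start]
            n_in_span = sum(1 for p in region.cpg_positions[i0:] if p < rec.end)
            if n_in_span != rec.n_cpgs:
                _record_error(
                    out, lineno,
                    f"pattern length {rec.n_cpgs} does not match {n_in_span} mapped "
                    f"CpGs in [{rec.start}, {rec.end}) of region {region.name}",
                    strict,
                )
                continue
            out.records.setdefault(region.name, []).append(rec)
    return out


def _record_error(out: SampleHaplotypeSet, lineno: int, msg: str, strict: bool) -> None:
    if strict:
        raise HaplotypeParseError(f"line {lineno}: {msg}")
    out.errors.append((lineno, msg))


def write_haplotypes(sample: SampleHaplotypeSet, path: str | Path) -> None:
    """Write a sample's records (mapped then unmapped) as mHap-style TSV.

    Output is sorted by coordinates so that identical record sets always
    serialize to identical bytes; ``read_haplotypes`` of the output
    reproduces the record multiset exactly.
    """
    recs = sorted(
        sample.all_records(),
        key=lambda r: (r.chrom, r.start, r.end, r.pattern, r.strand),
    )
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.pattern}\t{r.count}\t{r.strand}\n")
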