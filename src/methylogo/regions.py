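"""Genomic interval sets: BED reading, promoter construction, intersection.

All intervals are 0-based half-open ``[start, end)``.  BED input is taken
as 0-based half-open; 1-based TSS tables are converted at the reader
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "Region",
    "RegionSet",
    "read_bed6",
    "read_tss",
    "make_promoter_regions",
    "intersect_regions",
]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end})"
            )
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered list of stranded half-open intervals."""

    regions: list[Region] = field(default_factory=list)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def total_length(self) -> int:
        return sum(len(r) for r in self.regions)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n"
                )


def read_bed6(path) -> RegionSet:
    """Read a BED6 file of stranded intervals (strand column required)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                regions.append(
                    Region(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    log.info("read %d intervals from %s", len(regions), path)
    return RegionSet(regions)


def read_tss(path, one_based: bool = False) -> list[tuple[str, int, str]]:
    """Read a chrom/pos/strand TSV of transcription start sites."""
    tss: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chrom, pos, strand = fields[0], int(fields[1]), fields[2]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            tss.append((chrom, pos - (1 if one_based else 0), strand))
    log.info("read %d TSS from %s", len(tss), path)
    return tss


def make_promoter_regions(
    tss: Iterable[tuple[str, int, str]],
    upstream: int = 1000,
    downstream: int = 200,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionSet:
    """Build promoter windows around TSSs (default 1000 bp upstream to
    200 bp downstream, strand-relative).

    For a ``+`` TSS at t the window is ``[t-upstream, t+downstream)``; for
    a ``-`` TSS it is the mirror image on the genome,
    ``[t-downstream+1, t+upstream+1)``, covering the same strand-relative
    bases.  Windows are clamped to the chromosome and dropped if empty
    after clamping.
    """
    chrom_sizes = chrom_sizes or {}
    regions: list[Region] = []
    for chrom, pos, strand in tss:
        size = chrom_sizes.get(chrom)
        if size is not None and not 0 <= pos < size:
            raise ValueError(f"TSS {chrom}:{pos} outside chromosome (size {size})")
        if strand == "+":
            start, end = pos - upstream, pos + downstream
        elif strand == "-":
            start, end = pos - downstream + 1, pos + upstream + 1
        else:
            raise ValueError(f"bad TSS strand {strand!r}")
        start = max(start, 0)
        if size is not None:
            end = min(end, size)
        if start < end:
            regions.append(Region(chrom, start, end, strand))
    return RegionSet(regions)


def intersect_regions(a: RegionSet, b: RegionSet, mode: str = "overlap-any") -> RegionSet:
    """Coordinate-preserving filter: the intervals of ``a`` that overlap
    (``overlap-any``, at least 1 bp under half-open semantics) or are fully
    contained in (``contained``) some interval of ``b``.
    """
    if mode not in ("overlap-any", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for r in b:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    kept: list[Region] = []
    for r in a:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        hits = tree.overlap(r.start, r.end)
        if mode == "overlap-any":
            if hits:
                kept.append(r)
        else:
            if any(h.begin <= r.start and r.end <= h.end for h in hits):
                kept.append(r)
    log.info("intersect (%s): kept %d of %d intervals", mode, len(kept), len(a))
    return RegionSet(kept)
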