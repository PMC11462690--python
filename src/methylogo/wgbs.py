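"""Reading WGBS methylation-call tables and merging replicates.

Methylation BED flavours differ in column layout and in whether levels are
fractions, percentages or methylated/unmethylated read counts, so parsing
is driven by a :class:`WgbsDialect`.  Three common dialects ship built in:

``generic``
    chrom, start, end, strand, level(%), depth — 0-based half-open.
``bedmethyl``
    the 11-column ENCODE bedMethyl layout (strand col 6, coverage col 10,
    percent methylation col 11).
``bismark``
    the per-cytosine report: chrom, pos (1-based), strand, count
    methylated, count unmethylated, context, trinucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "CytosineCall",
    "WgbsDialect",
    "DIALECTS",
    "MethylTable",
    "read_wgbs_bed",
    "merge_replicates",
]

SiteKey = tuple[str, int, str]  # (chrom, 0-based pos, strand)


@dataclass(frozen=True)
class CytosineCall:
    """One per-cytosine observation: methylation fraction plus read depth."""

    chrom: str
    pos: int  # 0-based position of the cytosine on its own strand
    strand: str  # '+' or '-'
    level: float  # fraction in [0, 1]
    depth: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level {self.level} outside [0, 1]")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class WgbsDialect:
    """Column mapping for one WGBS table flavour (0-based column indices)."""

    chrom_col: int
    pos_col: int
    strand_col: int
    one_based: bool = False
    level_col: int | None = None
    level_scale: str = "percent"  # 'percent' or 'fraction'
    depth_col: int | None = None
    # counts mode: level and depth derived from methylated/unmethylated reads
    count_meth_col: int | None = None
    count_unmeth_col: int | None = None

    def parse_row(self, fields: list[str]) -> CytosineCall:
        chrom = fields[self.chrom_col]
        pos = int(fields[self.pos_col]) - (1 if self.one_based else 0)
        strand = fields[self.strand_col]
        if self.count_meth_col is not None:
            meth = int(fields[self.count_meth_col])
            unmeth = int(fields[self.count_unmeth_col])
            depth = meth + unmeth
            level = meth / depth if depth else 0.0
        else:
            level = float(fields[self.level_col])
            if self.level_scale == "percent":
                level /= 100.0
            depth = int(fields[self.depth_col])
        return CytosineCall(chrom, pos, strand, level, depth)


DIALECTS: Mapping[str, WgbsDialect] = {
    "generic": WgbsDialect(
        chrom_col=0, pos_col=1, strand_col=3, level_col=4, depth_col=5
    ),
    "bedmethyl": WgbsDialect(
        chrom_col=0, pos_col=1, strand_col=5, level_col=10, depth_col=9
    ),
    "bismark": WgbsDialect(
        chrom_col=0,
        pos_col=1,
        strand_col=2,
        one_based=True,
        count_meth_col=3,
        count_unmeth_col=4,
    ),
}


def read_wgbs_bed(path, dialect: str | WgbsDialect = "bedmethyl") -> list[CytosineCall]:
    """Parse one replicate's methylation calls under the given dialect.

    Raises with the 1-based line number on any level outside [0, 1] after
    scaling, unknown strand symbol, or duplicated (chrom, pos, strand).
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    calls: list[CytosineCall] = []
    seen: set[SiteKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                call = dialect.parse_row(line.split("\t"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if call.key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate site {call.key}"
                )
            seen.add(call.key)
            calls.append(call)
    log.info("read %d methylation calls from %s", len(calls), path)
    return calls


class MethylTable(dict):
    """Merged per-cytosine methylation levels, keyed by (chrom, pos, strand).

    Contains only sites that passed the read-depth filter during merging.
    """

    def level(self, chrom: str, pos: int, strand: str) -> float | None:
        return self.get((chrom, pos, strand))


def merge_replicates(
    replicates: Iterable[list[CytosineCall]],
    min_depth: int = 5,
    require_all: bool = False,
) -> MethylTable:
    """Depth-filter each replicate, then average levels per site.

    A site is retained in a replicate iff its read depth is at least
    ``min_depth`` (default 5, i.e. depth strictly greater than four).  The
    merged level is the unweighted mean over the replicates in which the
    site passed; with ``require_all`` it must pass in every replicate.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("merge_replicates needs at least one replicate")
    n_reps = len(replicates)
    sums: dict[SiteKey, float] = {}
    counts: dict[SiteKey, int] = {}
    dropped = 0
    for calls in replicates:
        for call in calls:
            if call.depth < min_depth:
                dropped += 1
                continue
            sums[call.key] = sums.get(call.key, 0.0) + call.level
            counts[call.key] = counts.get(call.key, 0) + 1
    table = MethylTable()
    for key, total in sums.items():
        k = counts[key]
        if require_all and k < n_reps:
            continue
        table[key] = total / k
    log.info(
        "merged %d replicates: %d sites kept, %d calls below depth %d",
        n_reps, len(table), dropped, min_depth,
    )
    return table
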