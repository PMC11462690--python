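"""Genome container, FASTA reading and cytosine context classification.

Coordinates are 0-based, half-open throughout.  A cytosine's trinucleotide
context (CG / CHG / CHH, H = A, C or T) is determined by the one or two
bases immediately downstream *on the cytosine's own strand*; this is a
genomic property, so classifying a cytosine near a region edge may require
bases outside the region of interest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "ContextLabel",
    "read_fasta",
    "classify_context",
    "revcomp",
]

_VALID = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved as upper)."""
    return seq.upper().translate(_COMP)[::-1]


class ContextLabel(str, enum.Enum):
    """Strand-relative trinucleotide context of a cytosine."""

    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNDEFINED = "UNDEFINED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the three defined contexts, in canonical display order
CONTEXTS = (ContextLabel.CG, ContextLabel.CHG, ContextLabel.CHH)


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name.

    Slices are strictly bounds-checked: requesting bases outside
    ``[0, chrom_length)`` raises instead of silently truncating, because a
    truncated context window would silently misclassify edge cytosines.
    """

    chroms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chroms = {name: seq.upper() for name, seq in self.chroms.items()}
        for name, seq in self.chroms.items():
            bad = set(seq) - _VALID
            if bad:
                pos = min(seq.index(c) for c in bad)
                raise ValueError(
                    f"non-IUPAC character {seq[pos]!r} in {name} at position {pos}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def _seq(self, chrom: str) -> str:
        try:
            return self.chroms[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; out-of-range access is an error."""
        seq = self._seq(chrom)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"slice [{start}, {end}) out of range for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.slice(chrom, pos, pos + 1)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into memory, normalising to uppercase.

    Raises on duplicate headers (naming the header) and on characters
    outside A/C/G/T/N (with the offending position).
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        chroms[rec.id] = str(rec.seq)
    return GenomeSequence(chroms)


def classify_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> ContextLabel:
    """Classify the cytosine at ``(chrom, pos, strand)``.

    ``pos`` is the 0-based genomic position of the cytosine base on its own
    strand: on ``+`` the genome shows ``C`` there, on ``-`` it shows ``G``.
    Reading downstream on the cytosine's strand: next base G gives CG;
    next base H then G gives CHG; two H's give CHH.  If the required
    downstream bases run off the chromosome or contain N the context is
    UNDEFINED.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    base = genome.base(chrom, pos)
    expected = "C" if strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"{chrom}:{pos}:{strand} is {base!r}, not a strand-relative C"
        )
    n = genome.length(chrom)
    if strand == "+":
        down1 = genome.base(chrom, pos + 1) if pos + 1 < n else None
        down2 = genome.base(chrom, pos + 2) if pos + 2 < n else None
    else:
        # downstream on '-' runs leftward on the genome, complemented
        down1 = revcomp(genome.base(chrom, pos - 1)) if pos - 1 >= 0 else None
        down2 = revcomp(genome.base(chrom, pos - 2)) if pos - 2 >= 0 else None

    if down1 is None or down1 == "N":
        return ContextLabel.UNDEFINED
    if down1 == "G":
        return ContextLabel.CG
    # down1 is H (A/C/T): need the second base
    if down2 is None or down2 == "N":
        return ContextLabel.UNDEFINED
    if down2 == "G":
        return ContextLabel.CHG
    return ContextLabel.CHH
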