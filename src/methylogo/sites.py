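"""Aligned binding-site matrix with per-cell methylation observations.

A :class:`SiteMatrix` stores N equal-length binding sites in *motif
orientation*: minus-strand sites are reverse-complemented so that column i
is homologous across sites.  In motif orientation a cell whose base is C
carries a cytosine on the motif-forward strand; a cell whose base is G
carries a cytosine on the motif-reverse strand.  For either kind of cell
the trinucleotide context is classified from the genomic neighbourhood
(context is a genomic property — a site-final C's context depends on bases
beyond the motif) and the merged methylation level is attached when the
site passed the WGBS depth filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import ContextLabel, GenomeSequence, classify_context
from .regions import RegionSet
from .wgbs import MethylTable

log = logging.getLogger(__name__)

__all__ = ["SiteMatrix", "extract_site_matrix", "CONTEXT_CODE", "CODE_CONTEXT"]

CONTEXT_CODE = {
    ContextLabel.CG: 0,
    ContextLabel.CHG: 1,
    ContextLabel.CHH: 2,
    ContextLabel.UNDEFINED: 3,
}
CODE_CONTEXT = {v: k for k, v in CONTEXT_CODE.items()}
NO_CONTEXT = -1

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SiteMatrix:
    """N aligned sites x (flank + motif + flank) columns, motif-oriented.

    Attributes
    ----------
    bases : (n, L + 2F) array of single characters, motif orientation.
    contexts : (n, L + 2F) int8 array; ``CONTEXT_CODE`` values where the
        cell holds a strand-relative cytosine (base C: motif ``+`` strand,
        base G: motif ``-`` strand), ``NO_CONTEXT`` elsewhere.
    levels : (n, L + 2F) float array; methylation level where observed,
        NaN where the site was absent from the :class:`MethylTable`.
    motif_length : L, the number of core motif columns.
    flank : F, columns on each side of the core; column j covers motif
        offset ``j - F``.
    strands : original genomic strand of each site ('+'/'-').
    """

    bases: np.ndarray
    contexts: np.ndarray
    levels: np.ndarray
    motif_length: int
    flank: int
    strands: list[str]

    @property
    def n_sites(self) -> int:
        return self.bases.shape[0]

    @property
    def width(self) -> int:
        return self.bases.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """Motif-relative offset of each column (0 .. L-1 is the core)."""
        return np.arange(self.width) - self.flank

    def core(self) -> "SiteMatrix":
        """The motif columns only (flank stripped, F = 0)."""
        sl = slice(self.flank, self.flank + self.motif_length)
        return SiteMatrix(
            self.bases[:, sl].copy(),
            self.contexts[:, sl].copy(),
            self.levels[:, sl].copy(),
            self.motif_length,
            0,
            list(self.strands),
        )

    def reverse_complement(self) -> "SiteMatrix":
        """The same sites read on the opposite strand.

        Column i maps to column width-1-i; C cells become G cells, so the
        motif-frame strand of every cytosine observation flips while its
        context and level are unchanged.
        """
        comp = np.vectorize(lambda b: b.translate(_COMP))(self.bases)
        return SiteMatrix(
            comp[:, ::-1].copy(),
            self.contexts[:, ::-1].copy(),
            self.levels[:, ::-1].copy(),
            self.motif_length,
            self.flank,
            ["-" if s == "+" else "+" for s in self.strands],
        )


def extract_site_matrix(
    genome: GenomeSequence,
    sites: RegionSet,
    methyl: MethylTable,
    flank: int = 2,
) -> SiteMatrix:
    """Assemble the aligned SiteMatrix from genomic site coordinates.

    All intervals must share one length L.  ``flank`` must be >= 2 because
    context classification of the last motif column can need two bases
    beyond it.  Sites whose flank window runs off the chromosome, and
    sites with N in the motif core, are dropped with a warning.
    """
    if flank < 2:
        raise ValueError("flank must be >= 2 (context lookup needs 2 bases)")
    if len(sites) == 0:
        raise ValueError("empty site set")
    lengths = {len(r) for r in sites}
    if len(lengths) != 1:
        offenders = [
            f"{r.chrom}:{r.start}-{r.end}" for r in sites
            if len(r) != max(lengths, key=lambda L: sum(len(x) == L for x in sites))
        ]
        raise ValueError(
            f"sites have heterogeneous lengths {sorted(lengths)}; "
            f"offenders include {offenders[:5]}"
        )
    L = lengths.pop()
    width = L + 2 * flank

    rows_b: list[list[str]] = []
    rows_c: list[list[int]] = []
    rows_m: list[list[float]] = []
    strands: list[str] = []
    n_edge = n_withN = 0

    for r in sites:
        lo, hi = r.start - flank, r.end + flank
        if lo < 0 or hi > genome.length(r.chrom):
            n_edge += 1
            continue
        if "N" in genome.slice(r.chrom, r.start, r.end):
            n_withN += 1
            continue
        strand = r.strand if r.strand in "+-" else "+"
        row_b, row_c, row_m = [], [], []
        for j in range(width):
            # genomic position of motif column j
            g = lo + j if strand == "+" else hi - 1 - j
            gbase = genome.base(r.chrom, g)
            base = gbase if strand == "+" else gbase.translate(_COMP)
            ctx_code, level = NO_CONTEXT, np.nan
            if base in "CG":
                # motif-frame '+' cytosine sits on the site's genomic
                # strand; motif-frame '-' on the opposite one
                if base == "C":
                    gstrand = strand
                else:
                    gstrand = "-" if strand == "+" else "+"
                ctx_code = CONTEXT_CODE[
                    classify_context(genome, r.chrom, g, gstrand)
                ]
                obs = methyl.get((r.chrom, g, gstrand))
                if obs is not None:
                    level = obs
            row_b.append(base)
            row_c.append(ctx_code)
            row_m.append(level)
        rows_b.append(row_b)
        rows_c.append(row_c)
        rows_m.append(row_m)
        strands.append(strand)

    if n_edge or n_withN:
        log.warning(
            "dropped %d sites too close to a chromosome edge and %d with N "
            "in the motif core", n_edge, n_withN,
        )
    if not rows_b:
        raise ValueError("no usable sites after edge/N filtering")
    return SiteMatrix(
        np.array(rows_b, dtype="U1"),
        np.array(rows_c, dtype=np.int8),
        np.array(rows_m, dtype=float),
        L,
        flank,
        strands,
    )
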