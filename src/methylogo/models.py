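"""Background models (zero-order, first-order, context methylation) and
the position-specific motif model.

Backgrounds are estimated over a region set — typically the whole genome or
promoter windows — counting *both strands*, which forces the A/T and C/G
symmetry a strand-agnostic background should have.  The first-order model
counts overlapping dimers within each contiguous covered block (a dimer and
its reverse complement contribute symmetrically; no dimer spans a region
boundary) and emits the first base of a sequence from the left marginal of
its joint, so that the dimer-track decomposition of the relative-entropy
difference between first- and zero-order backgrounds is exact.

Motif-side statistics stay strand-resolved: per position the model records
the probability of a cytosine in each (context, strand) class and the mean
methylation of that class, since forward- and reverse-strand cytosines of
a motif are displayed separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import CONTEXTS, ContextLabel, GenomeSequence, classify_context, revcomp
from .regions import Region, RegionSet
from .sites import CONTEXT_CODE, SiteMatrix
from .wgbs import MethylTable

log = logging.getLogger(__name__)

__all__ = [
    "BASES",
    "ZeroOrderBackground",
    "FirstOrderBackground",
    "MethylationBackground",
    "MotifModel",
    "BackgroundBundle",
    "estimate_zero_order",
    "estimate_first_order",
    "estimate_methyl_background",
    "build_motif_model",
]

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
EPS = 1e-4  # clamp for probabilities entering binary KL
STRANDS = "+-"


def _check_simplex(p: np.ndarray, what: str) -> None:
    # zeros are tolerated (a user may disable smoothing); the default
    # pseudocounts keep estimated backgrounds strictly positive
    if abs(float(p.sum()) - 1.0) > 1e-12:
        raise ValueError(f"{what} does not sum to 1 (sum={p.sum()!r})")
    if (p < 0).any():
        raise ValueError(f"{what} has negative entries")


@dataclass
class ZeroOrderBackground:
    """Independent-base background: q(b) for b in ACGT."""

    q: np.ndarray  # shape (4,)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        _check_simplex(self.q, "zero-order background")

    def prob(self, base: str) -> float:
        return float(self.q[_IDX[base]])

    def as_dict(self) -> dict[str, float]:
        return {b: float(self.q[i]) for i, b in enumerate(BASES)}


@dataclass
class FirstOrderBackground:
    """First-order Markov background: joint dimer probabilities q(a, b).

    The chain emits its first base from the left marginal of the joint and
    each subsequent base from q(b|a) = q(a,b) / sum_b' q(a,b').
    """

    joint: np.ndarray  # shape (4, 4), q(a, b)

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        _check_simplex(self.joint.ravel(), "first-order background joint")

    @property
    def marginal(self) -> np.ndarray:
        """Left marginal q(a) = sum_b q(a, b)."""
        return self.joint.sum(axis=1)

    @property
    def conditional(self) -> np.ndarray:
        """q(b|a) as a (4, 4) row-stochastic matrix (uniform on never-seen
        previous bases)."""
        marg = self.marginal[:, None]
        return np.where(marg > 0, self.joint / np.where(marg > 0, marg, 1.0), 0.25)

    def marginal_zero_order(self) -> ZeroOrderBackground:
        return ZeroOrderBackground(self.marginal.copy())

    def symmetric_marginal_zero_order(self) -> ZeroOrderBackground:
        """The left marginal averaged with its complement.

        Linear dimer counting leaves the left marginal strand-symmetric
        only up to per-block boundary terms; averaging q(a) with q(rc(a))
        (index reversal in ACGT order) removes them exactly, at the cost
        of an O(1/coverage) deviation from the exact pair decomposition.
        """
        m = self.marginal
        return ZeroOrderBackground(0.5 * (m + m[::-1]))

    def prob(self, a: str, b: str) -> float:
        return float(self.joint[_IDX[a], _IDX[b]])


@dataclass
class MethylationBackground:
    """Background probability that a cytosine of each context is methylated."""

    m: dict[ContextLabel, float]
    counts: dict[ContextLabel, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m = {
            ContextLabel(ctx): min(max(float(v), EPS), 1.0 - EPS)
            for ctx, v in self.m.items()
        }
        for ctx in CONTEXTS:
            if ctx not in self.m:
                raise ValueError(f"missing background methylation for {ctx}")

    def prob(self, ctx: ContextLabel) -> float:
        return self.m[ContextLabel(ctx)]


@dataclass
class MotifModel:
    """Position-specific model of a set of aligned binding sites.

    Attributes
    ----------
    p : (L, 4) per-position base probabilities.
    pair : (L-1, 4, 4) adjacent-position joint base probabilities.
    ctx_prob : (L, 3, 2) probability that a site carries a cytosine of
        context (CG, CHG, CHH) on strand (+, -) at each position, with
        UNDEFINED-context cells excluded from numerator and denominator.
    meth_mean : (L, 3, 2) mean methylation of each class; NaN where the
        class has cytosines but no level passed the WGBS depth filter.
    n_sites : number of sites the counts came from.
    """

    p: np.ndarray
    pair: np.ndarray
    ctx_prob: np.ndarray
    meth_mean: np.ndarray
    n_sites: int

    @property
    def length(self) -> int:
        return self.p.shape[0]


def _covered_blocks(
    genome: GenomeSequence, regions: RegionSet | None
) -> list[str]:
    if regions is None:
        return [genome.chroms[name] for name in genome.names]
    if len(regions) == 0:
        raise ValueError("empty region set")
    return [genome.slice(r.chrom, r.start, r.end) for r in regions]


def estimate_zero_order(
    genome: GenomeSequence,
    regions: RegionSet | None = None,
    pseudocount: float = 1.0,
) -> ZeroOrderBackground:
    """Base frequencies over both strands of the covered sequence.

    ``regions=None`` means the whole genome.  N bases are skipped.
    Counting both strands makes q(A)=q(T) and q(C)=q(G) exactly.
    """
    counts = np.zeros(4)
    for block in _covered_blocks(genome, regions):
        for i, b in enumerate(BASES):
            counts[i] += block.count(b)
    # the reverse strand contributes the complement of every counted base
    both = counts + counts[::-1]
    if both.sum() == 0:
        raise ValueError("regions cover zero non-N bases")
    both += pseudocount
    return ZeroOrderBackground(both / both.sum())


def estimate_first_order(
    genome: GenomeSequence,
    regions: RegionSet | None = None,
    pseudocount: float = 1.0,
) -> FirstOrderBackground:
    """Joint dimer frequencies from overlapping dimers in each covered block.

    Every dimer contributes to q(a,b) and its reverse complement to
    q(rc(b), rc(a)); dimers containing N, and dimers spanning region
    boundaries, are not counted.
    """
    counts = np.zeros((4, 4))
    for block in _covered_blocks(genome, regions):
        for k in range(len(block) - 1):
            a, b = block[k], block[k + 1]
            if a == "N" or b == "N":
                continue
            counts[_IDX[a], _IDX[b]] += 1
            counts[_IDX[revcomp(b)], _IDX[revcomp(a)]] += 1
    if counts.sum() == 0:
        raise ValueError("regions contain no countable dimers")
    counts += pseudocount
    return FirstOrderBackground(counts / counts.sum())


def estimate_methyl_background(
    methyl: MethylTable,
    genome: GenomeSequence,
    regions: RegionSet | None = None,
) -> MethylationBackground:
    """Mean methylation level per context over the table entries inside the
    regions, both strands pooled; clamped away from 0 and 1.

    Raises if any of CG/CHG/CHH has no contributing cytosine — a
    background with an undefined context cannot be used for the
    methylation track.
    """
    if not methyl:
        raise ValueError("empty methylation table")
    inside = None
    if regions is not None:
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for r in regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

        def inside(chrom: str, pos: int) -> bool:
            tree = trees.get(chrom)
            return tree is not None and bool(tree.overlap(pos, pos + 1))

    sums = {ctx: 0.0 for ctx in CONTEXTS}
    counts = {ctx: 0 for ctx in CONTEXTS}
    for (chrom, pos, strand), level in methyl.items():
        if inside is not None and not inside(chrom, pos):
            continue
        ctx = classify_context(genome, chrom, pos, strand)
        if ctx is ContextLabel.UNDEFINED:
            continue
        sums[ctx] += level
        counts[ctx] += 1
    for ctx in CONTEXTS:
        if counts[ctx] == 0:
            raise ValueError(
                f"no {ctx} cytosines in the regions; supply a prior or "
                f"larger regions"
            )
    m = {ctx: sums[ctx] / counts[ctx] for ctx in CONTEXTS}
    log.info(
        "methylation background: %s",
        {str(c): (round(m[c], 4), counts[c]) for c in CONTEXTS},
    )
    return MethylationBackground(m, counts)


def build_motif_model(sites: SiteMatrix, pseudocount: float = 0.5) -> MotifModel:
    """Estimate the motif model from the aligned core columns.

    ``pseudocount`` is added to every base cell and every dimer cell.
    Context/methylation statistics use raw fractions (no pseudocount): the
    multiplicative context-probability term already damps rare classes.
    """
    core = sites.core() if sites.flank else sites
    n, L = core.n_sites, core.motif_length
    if n < 1:
        raise ValueError("empty site matrix")

    base_idx = np.zeros((n, L), dtype=int)
    for b, i in _IDX.items():
        base_idx[core.bases == b] = i

    p = np.zeros((L, 4))
    for i in range(L):
        cnt = np.bincount(base_idx[:, i], minlength=4).astype(float)
        cnt += pseudocount
        p[i] = cnt / cnt.sum()

    pair = np.zeros((max(L - 1, 0), 4, 4))
    for i in range(L - 1):
        cnt = np.zeros((4, 4))
        np.add.at(cnt, (base_idx[:, i], base_idx[:, i + 1]), 1.0)
        cnt += pseudocount
        pair[i] = cnt / cnt.sum()

    ctx_prob = np.zeros((L, 3, 2))
    meth_mean = np.full((L, 3, 2), np.nan)
    undef = CONTEXT_CODE[ContextLabel.UNDEFINED]
    for i in range(L):
        col_ctx = core.contexts[:, i]
        col_base = core.bases[:, i]
        col_lvl = core.levels[:, i]
        denom = int((col_ctx != undef).sum())  # UNDEFINED excluded entirely
        if denom == 0:
            continue
        for ctx in CONTEXTS:
            code = CONTEXT_CODE[ctx]
            for s, sbase in enumerate(("C", "G")):  # + strand holds C cells
                mask = (col_ctx == code) & (col_base == sbase)
                k = int(mask.sum())
                if k == 0:
                    continue
                ctx_prob[i, code, s] = k / denom
                lvls = col_lvl[mask]
                lvls = lvls[~np.isnan(lvls)]
                if lvls.size:
                    meth_mean[i, code, s] = float(lvls.mean())

    return MotifModel(p, pair, ctx_prob, meth_mean, n)


@dataclass
class BackgroundBundle:
    """The three background models for one region set, serializable to JSON
    so backgrounds can be precomputed once and reused across logos."""

    bg0: ZeroOrderBackground
    bg1: FirstOrderBackground
    mbg: MethylationBackground
    provenance: dict = field(default_factory=dict)

    @classmethod
    def estimate(
        cls,
        genome: GenomeSequence,
        methyl: MethylTable,
        regions: RegionSet | None = None,
        pseudocount: float = 1.0,
        label: str = "WG",
    ) -> "BackgroundBundle":
        """Estimate all three models over one region set.

        bg0 is taken as the left marginal of bg1's joint so that the
        dimer track decomposes the first-vs-zero-order relative-entropy
        difference exactly.
        """
        bg1 = estimate_first_order(genome, regions, pseudocount)
        bg0 = bg1.symmetric_marginal_zero_order()
        mbg = estimate_methyl_background(methyl, genome, regions)
        prov = {
            "label": label,
            "regions": "whole-genome" if regions is None else f"{len(regions)} intervals",
            "covered_bp": (
                sum(genome.lengths.values()) if regions is None
                else regions.total_length()
            ),
            "context_counts": {str(c): mbg.counts.get(c, 0) for c in CONTEXTS},
            "pseudocount": pseudocount,
        }
        return cls(bg0, bg1, mbg, prov)

    def to_dict(self) -> dict:
        return {
            "base_frequencies": self.bg0.as_dict(),
            "dimer_joint": {
                a: {b: self.bg1.prob(a, b) for b in BASES} for a in BASES
            },
            "context_methylation": {str(c): self.mbg.m[c] for c in CONTEXTS},
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "BackgroundBundle":
        with open(path) as fh:
            d = json.load(fh)
        bg0 = ZeroOrderBackground(np.array([d["base_frequencies"][b] for b in BASES]))
        bg1 = FirstOrderBackground(
            np.array([[d["dimer_joint"][a][b] for b in BASES] for a in BASES])
        )
        mbg = MethylationBackground(
            {ContextLabel(k): v for k, v in d["context_methylation"].items()}
        )
        return cls(bg0, bg1, mbg, d.get("provenance", {}))
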