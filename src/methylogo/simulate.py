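"""Synthetic genomes, methylomes and planted binding sites with known truth.

Everything the pipeline consumes can be generated here: a genome drawn
from a zero- or first-order Markov chain, a per-cytosine methylome whose
true level depends on trinucleotide context (overridable inside planted
sites), two replicate WGBS call files with binomial sampling noise at a
configurable read depth, a BED6 of planted site coordinates and a TSS
table.  All draws come from one seeded generator, so a fixed seed
reproduces every output byte for byte.

Methylation calls are simulated at the call level (level + depth), not at
the read level: no FASTQ, no alignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import GenomeSequence
from .regions import Region, RegionSet

log = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "simulate_genome",
    "simulate_methylome",
    "plant_sites",
    "simulate_tss",
    "simulate_dataset",
    "cg_depleted_transition",
]


def cg_depleted_transition(depletion: float = 0.25,
                           base_probs=(0.3, 0.2, 0.2, 0.3)) -> list[list[float]]:
    """A first-order transition matrix with the CpG step suppressed.

    Starting from independent emissions with the given base probabilities
    (ACGT order), P(G | C) is multiplied by ``depletion`` and the C row
    renormalised — a minimal emulation of the CpG depletion that makes a
    first-order background informative for CpG-containing motifs.
    """
    p = np.asarray(base_probs, dtype=float)
    p = p / p.sum()
    T = np.tile(p, (4, 1))
    T[1, 2] *= depletion  # C -> G
    T[1] /= T[1].sum()
    return T.tolist()

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimulationSpec:
    """Ground-truth parameters for one synthetic dataset.

    Defaults emulate a mammalian-like study condition: CG-depleted
    first-order genome, hyper-methylated CG context (0.8) against
    near-unmethylated CHG/CHH (0.05 / 0.02), read depth 30, and a
    palindromic CpG-containing E-box consensus planted at 200 sites.
    """

    seed: int
    genome_length: int = 100_000
    chrom: str = "chr1"
    base_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    # conditional P(next | prev) rows in ACGT order; None = zero-order
    transition: list[list[float]] | None = None
    context_meth: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.05, "CHH": 0.02}
    )
    depth_mean: int = 30
    depth_distribution: str = "fixed"  # 'fixed' or 'poisson'
    motif_consensus: str = "CACGTG"
    # per-position base distributions; None = consensus planted exactly
    motif_pwm: list[list[float]] | None = None
    n_sites: int = 200
    site_meth: float | dict[int, float] | None = None
    site_strands: str = "both"  # '+', '-' or 'both'
    site_margin: int = 20  # exclusion margin so context windows never collide
    n_tss: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for v in self.context_meth.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("context methylation must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def simulate_genome(spec: SimulationSpec) -> GenomeSequence:
    """Draw one chromosome from the specified Markov chain."""
    n = spec.genome_length
    if n <= 0:
        raise ValueError("genome length must be positive")
    rng = spec.rng(stream=1)
    p0 = np.asarray(spec.base_probs, dtype=float)
    p0 = p0 / p0.sum()
    if spec.transition is None:
        idx = rng.choice(4, size=n, p=p0)
    else:
        T = np.asarray(spec.transition, dtype=float)
        T = T / T.sum(axis=1, keepdims=True)
        cum = T.cumsum(axis=1)
        u = rng.random(n)
        idx = np.empty(n, dtype=np.int64)
        idx[0] = rng.choice(4, p=p0)
        for i in range(1, n):  # sequential chain; ~1e6 steps is fine
            idx[i] = np.searchsorted(cum[idx[i - 1]], u[i], side="right")
    seq = "".join(BASES[i] for i in idx)
    return GenomeSequence({spec.chrom: seq})


def plant_sites(
    genome: GenomeSequence, spec: SimulationSpec
) -> tuple[GenomeSequence, RegionSet]:
    """Plant n non-overlapping binding sites, returning the modified genome
    and their BED-style coordinates.

    Sites are drawn from the per-position base distribution (or the
    consensus verbatim), placed with an exclusion margin so flank/context
    windows never collide, on random strands per ``site_strands``; a
    minus-strand site is written as the reverse complement so reading the
    interval on '-' recovers the drawn sequence.
    """
    rng = spec.rng(stream=2)
    L = len(spec.motif_consensus)
    if spec.motif_pwm is not None:
        pwm = np.asarray(spec.motif_pwm, dtype=float)
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
        if pwm.shape != (L, 4):
            raise ValueError("motif_pwm must be (motif length, 4)")
    chrom = spec.chrom
    n_bp = genome.length(chrom)
    if L > n_bp:
        raise ValueError("motif longer than genome")
    margin = spec.site_margin
    stride = L + 2 * margin
    starts_all = np.arange(margin, n_bp - L - margin, stride)
    if len(starts_all) < spec.n_sites:
        raise ValueError(
            f"cannot place {spec.n_sites} non-overlapping sites "
            f"(room for {len(starts_all)})"
        )
    chosen = np.sort(rng.choice(starts_all, size=spec.n_sites, replace=False))

    seq = list(genome.chroms[chrom])
    regions: list[Region] = []
    for k, start in enumerate(chosen):
        if spec.motif_pwm is None:
            site = spec.motif_consensus
        else:
            site = "".join(
                BASES[rng.choice(4, p=pwm[i])] for i in range(L)
            )
        if spec.site_strands == "both":
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            strand = spec.site_strands
        written = site if strand == "+" else _revcomp(site)
        seq[start : start + L] = written
        regions.append(Region(chrom, int(start), int(start) + L, strand, f"site{k}"))
    new_genome = GenomeSequence({chrom: "".join(seq)})
    return new_genome, RegionSet(regions)


def _cytosine_truth(
    genome: GenomeSequence, spec: SimulationSpec, planted: RegionSet | None
) -> list[tuple[str, int, str, float]]:
    """True methylation level of every context-defined cytosine, both
    strands, with planted-site overrides applied by motif offset."""
    override: dict[int, float | dict[int, float]] = {}
    site_frame: dict[int, tuple[int, str]] = {}
    if planted is not None and spec.site_meth is not None:
        for r in planted:
            for g in range(r.start, r.end):
                off = g - r.start if r.strand != "-" else r.end - 1 - g
                site_frame[g] = (off, r.strand)

    out = []
    for chrom in genome.names:
        seq = genome.chroms[chrom]
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand in "+-":
            c_base = b"C" if strand == "+" else b"G"
            positions = np.nonzero(arr == c_base)[0]
            for p in positions:
                p = int(p)
                if strand == "+":
                    if p + 1 >= n:
                        continue
                    d1 = seq[p + 1]
                    d2 = seq[p + 2] if p + 2 < n else None
                else:
                    if p - 1 < 0:
                        continue
                    d1 = seq[p - 1].translate(_COMP)
                    d2 = seq[p - 2].translate(_COMP) if p - 2 >= 0 else None
                if d1 == "G":
                    ctx = "CG"
                elif d2 is None:
                    continue
                elif d2 == "G":
                    ctx = "CHG"
                else:
                    ctx = "CHH"
                level = spec.context_meth[ctx]
                if p in site_frame:
                    off, _ = site_frame[p]
                    if isinstance(spec.site_meth, dict):
                        level = spec.site_meth.get(off, level)
                    elif spec.site_meth is not None:
                        level = spec.site_meth
                out.append((chrom, p, strand, level))
    return out


def simulate_methylome(
    genome: GenomeSequence,
    spec: SimulationSpec,
    outdir,
    planted: RegionSet | None = None,
    n_replicates: int = 2,
) -> list[Path]:
    """Write replicate WGBS call files (generic dialect) with binomial noise.

    Per replicate and cytosine, depth is fixed at ``depth_mean`` or drawn
    Poisson(depth_mean), and the observed level is
    Binomial(depth, true level) / depth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = _cytosine_truth(genome, spec, planted)
    rng = spec.rng(stream=3)
    paths = []
    for rep in range(1, n_replicates + 1):
        path = outdir / f"wgbs_rep{rep}.tsv"
        levels = np.array([t[3] for t in truth])
        if spec.depth_distribution == "poisson":
            depths = rng.poisson(spec.depth_mean, size=len(truth))
        else:
            depths = np.full(len(truth), spec.depth_mean, dtype=int)
        meth_reads = rng.binomial(depths, levels)
        with open(path, "w") as fh:
            for (chrom, pos, strand, _), d, k in zip(truth, depths, meth_reads):
                obs = 100.0 * k / d if d else 0.0
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{strand}\t{obs:.6g}\t{d}\n")
        paths.append(path)
    log.info("wrote %d replicates x %d cytosines", n_replicates, len(truth))
    return paths


def simulate_tss(genome: GenomeSequence, spec: SimulationSpec) -> list[tuple[str, int, str]]:
    """Random TSS positions (for promoter-background construction)."""
    rng = spec.rng(stream=4)
    chrom = spec.chrom
    n = genome.length(chrom)
    lo, hi = min(2000, n // 4), max(n - 2000, n * 3 // 4)
    pos = np.sort(rng.integers(lo, hi, size=spec.n_tss))
    strands = rng.choice(list("+-"), size=spec.n_tss)
    return [(chrom, int(p), str(s)) for p, s in zip(pos, strands)]


def simulate_dataset(spec: SimulationSpec, outdir) -> dict:
    """Generate a complete dataset on disk; returns a manifest dict.

    Writes genome.fa, wgbs_rep1/2.tsv, sites.bed, tss.tsv and
    manifest.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(spec)
    genome, sites = plant_sites(genome, spec)
    genome.write_fasta(outdir / "genome.fa")
    sites.write_bed(outdir / "sites.bed")
    wgbs_paths = simulate_methylome(genome, spec, outdir, planted=sites)
    tss = simulate_tss(genome, spec)
    with open(outdir / "tss.tsv", "w") as fh:
        for chrom, pos, strand in tss:
            fh.write(f"{chrom}\t{pos}\t{strand}\n")
    manifest = {
        "spec": asdict(spec),
        "files": {
            "genome": "genome.fa",
            "wgbs": [p.name for p in wgbs_paths],
            "sites": "sites.bed",
            "tss": "tss.tsv",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
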