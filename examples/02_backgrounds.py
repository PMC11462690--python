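"""Estimate background models: base/dimer frequencies and per-context
methylation, whole-genome versus promoter regions.

Backgrounds are the reference the information tracks are measured
against; they serialize to JSON so they can be computed once per
cell type and reused for many logos.
"""

from pathlib import Path

from methylogo import (
    BackgroundBundle,
    make_promoter_regions,
    merge_replicates,
    read_fasta,
    read_tss,
    read_wgbs_bed,
)

data = Path("examples/output/dataset")
if not data.exists():
    raise SystemExit("run examples/01_simulate_dataset.py first")

genome = read_fasta(data / "genome.fa")
methyl = merge_replicates(
    [read_wgbs_bed(data / f"wgbs_rep{i}.tsv", "generic") for i in (1, 2)]
)
print(f"{len(methyl)} cytosines passed the depth > 4 filter")

wg = BackgroundBundle.estimate(genome, methyl, label="WG")
promoters = make_promoter_regions(
    read_tss(data / "tss.tsv"), chrom_sizes=genome.lengths
)
pr = BackgroundBundle.estimate(genome, methyl, promoters, label="PR")

for bundle in (wg, pr):
    label = bundle.provenance["label"]
    q = bundle.bg0.as_dict()
    print(f"\n[{label}] base frequencies: "
          + "  ".join(f"{b}={v:.3f}" for b, v in q.items()))
    print(f"[{label}] P(G follows C): {bundle.bg1.conditional[1, 2]:.4f} "
          f"(vs {q['G']:.3f} if independent -> CpG depletion)")
    print(f"[{label}] context methylation: "
          + "  ".join(f"{c}={v:.3f}" for c, v in bundle.mbg.m.items()))

wg.save(data / "background_wg.json")
print(f"\nwrote {data / 'background_wg.json'}")
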