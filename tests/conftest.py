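import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from methylogo import (
    BackgroundBundle,
    SimulationSpec,
    build_motif_model,
    cg_depleted_transition,
    extract_site_matrix,
    merge_replicates,
    plant_sites,
    read_wgbs_bed,
    simulate_genome,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """A small simulated study: CG-depleted genome, hyper-methylated CG
    background, 100 hypo-methylated planted E-box (CACGTG) sites."""
    outdir = tmp_path_factory.mktemp("planted")
    spec = SimulationSpec(
        seed=11,
        genome_length=80_000,
        n_sites=100,
        motif_consensus="CACGTG",
        site_meth=0.05,
        transition=cg_depleted_transition(0.2),
        site_margin=25,
    )
    genome = simulate_genome(spec)
    genome, sites = plant_sites(genome, spec)
    wgbs = simulate_methylome(genome, spec, outdir, planted=sites)
    methyl = merge_replicates([read_wgbs_bed(p, "generic") for p in wgbs])
    return {
        "spec": spec,
        "genome": genome,
        "sites": sites,
        "methyl": methyl,
        "outdir": outdir,
        "wgbs": wgbs,
    }


@pytest.fixture(scope="session")
def planted_model(planted_dataset):
    d = planted_dataset
    bundle = BackgroundBundle.estimate(d["genome"], d["methyl"])
    matrix = extract_site_matrix(d["genome"], d["sites"], d["methyl"], flank=10)
    motif = build_motif_model(matrix)
    return {"bundle": bundle, "matrix": matrix, "motif": motif, **d}
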