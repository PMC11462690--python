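import numpy as np
import pytest

from methylogo import (
    BackgroundBundle,
    ContextLabel,
    GenomeSequence,
    MethylTable,
    Region,
    RegionSet,
    build_motif_model,
    estimate_first_order,
    estimate_methyl_background,
    estimate_zero_order,
    extract_site_matrix,
    revcomp,
)
from methylogo.models import BASES, EPS
from methylogo.sites import CONTEXT_CODE


def region_over(genome, chrom="chr1"):
    return RegionSet([Region(chrom, 0, genome.length(chrom))])


class TestZeroOrder:
    def test_hand_count_double_stranded(self):
        # "AACT" + its reverse complement "AGTT": A 3, C 1, G 1, T 3 of 8
        g = GenomeSequence({"chr1": "AACT"})
        bg = estimate_zero_order(g, pseudocount=0.0)
        assert bg.prob("A") == pytest.approx(3 / 8)
        assert bg.prob("T") == pytest.approx(3 / 8)
        assert bg.prob("C") == pytest.approx(1 / 8)
        assert bg.prob("G") == pytest.approx(1 / 8)
        # and a sequence whose complement evens everything out
        bg2 = estimate_zero_order(GenomeSequence({"c": "AACG"}), pseudocount=0.0)
        assert np.allclose(bg2.q, 0.25)

    def test_uniform_genome_recovery(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        bg = estimate_zero_order(GenomeSequence({"c": seq}))
        assert np.allclose(bg.q, 0.25, atol=0.01)

    def test_strand_symmetry_exact(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.3, 0.2, 0.1], size=5000))
        bg = estimate_zero_order(GenomeSequence({"c": seq}))
        assert bg.prob("A") == pytest.approx(bg.prob("T"), abs=1e-15)
        assert bg.prob("C") == pytest.approx(bg.prob("G"), abs=1e-15)

    def test_empty_regions_error(self):
        g = GenomeSequence({"chr1": "ACGT"})
        with pytest.raises(ValueError):
            estimate_zero_order(g, RegionSet())

    def test_all_n_error(self):
        with pytest.raises(ValueError, match="zero non-N"):
            estimate_zero_order(GenomeSequence({"c": "NNNN"}), pseudocount=0.0)


class TestFirstOrder:
    def test_single_cg_region_hand_count(self):
        g = GenomeSequence({"chr1": "CG"})
        bg = estimate_first_order(g, pseudocount=0.0)
        # one '+' CG dimer and one '-' CG dimer (its own revcomp)
        assert bg.prob("C", "G") == pytest.approx(1.0)

    def test_independent_chain_factorizes(self):
        rng = np.random.default_rng(2)
        p = np.array([0.3, 0.2, 0.2, 0.3])
        seq = "".join(rng.choice(list("ACGT"), p=p, size=200_000))
        bg = estimate_first_order(GenomeSequence({"c": seq}))
        outer = np.outer(bg.marginal, bg.marginal)
        assert np.allclose(bg.joint, outer, atol=0.005)

    def test_no_dimers_across_region_boundaries(self):
        g = GenomeSequence({"chr1": "CGCG"})
        # two disjoint 1-bp regions contain no dimer at all
        with pytest.raises(ValueError, match="no countable dimers"):
            estimate_first_order(
                g, RegionSet([Region("chr1", 0, 1), Region("chr1", 2, 3)]),
                pseudocount=0.0,
            )

    def test_revcomp_genome_invariance(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.25, 0.2, 0.15], size=3000))
        g1 = GenomeSequence({"c": seq})
        g2 = GenomeSequence({"c": revcomp(seq)})
        b1 = estimate_first_order(g1, pseudocount=0.0)
        b2 = estimate_first_order(g2, pseudocount=0.0)
        assert np.allclose(b1.joint, b2.joint, atol=1e-15)
        z1 = estimate_zero_order(g1, pseudocount=0.0)
        z2 = estimate_zero_order(g2, pseudocount=0.0)
        assert np.allclose(z1.q, z2.q, atol=1e-15)

    def test_normalization_and_conditional(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        bg = estimate_first_order(GenomeSequence({"c": seq}))
        assert bg.joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(bg.conditional.sum(axis=1), 1.0, atol=1e-12)
        assert (bg.joint > 0).all()


class TestMethylBackground:
    def _table(self, genome, levels):
        """MethylTable over every context-defined cytosine of the genome."""
        from oracles import scan_contexts

        table = MethylTable()
        for chrom in genome.names:
            for (pos, strand), ctx in scan_contexts(genome.chroms[chrom]).items():
                table[(chrom, pos, strand)] = levels[ctx]
        return table

    def test_recovery_of_context_means(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        g = GenomeSequence({"c": seq})
        truth = {"CG": 0.8, "CHG": 0.05, "CHH": 0.02}
        mbg = estimate_methyl_background(self._table(g, truth), g)
        for ctx, v in truth.items():
            assert mbg.prob(ContextLabel(ctx)) == pytest.approx(v, abs=1e-9)

    def test_saturated_level_clamped(self):
        g = GenomeSequence({"c": "ACGTT"})
        table = MethylTable({("c", 1, "+"): 1.0, ("c", 2, "-"): 1.0})
        # only CG cytosines exist; CHG/CHH cannot be estimated here
        with pytest.raises(ValueError, match="CHG|CHH"):
            estimate_methyl_background(table, g)

    def test_clamp_applied(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        g = GenomeSequence({"c": seq})
        mbg = estimate_methyl_background(
            self._table(g, {"CG": 1.0, "CHG": 0.0, "CHH": 0.5}), g
        )
        assert mbg.prob(ContextLabel.CG) == pytest.approx(1.0 - EPS)
        assert mbg.prob(ContextLabel.CHG) == pytest.approx(EPS)

    def test_regions_excluding_a_context_error(self):
        g = GenomeSequence({"c": "AACGAA" + "A" * 10})
        table = MethylTable({("c", 2, "+"): 0.5, ("c", 3, "-"): 0.5})
        with pytest.raises(ValueError, match="CHG"):
            estimate_methyl_background(table, g)


class TestMotifModel:
    def _matrix(self, genome_seq, intervals):
        g = GenomeSequence({"chr1": genome_seq})
        rs = RegionSet([Region("chr1", s, e, st) for s, e, st in intervals])
        return g, extract_site_matrix(g, rs, MethylTable(), flank=2)

    def test_all_cg_sites_direct_construction(self):
        seq = "AACGAAACGAAACGAAACGAA"
        ivals = [(2, 4, "+"), (7, 9, "+"), (12, 14, "+"), (17, 19, "+")]
        _, sm = self._matrix(seq, ivals)
        m = build_motif_model(sm, pseudocount=0.0)
        assert m.p[0, BASES.index("C")] == pytest.approx(1.0)
        assert m.p[1, BASES.index("G")] == pytest.approx(1.0)
        assert m.pair[0, BASES.index("C"), BASES.index("G")] == pytest.approx(1.0)
        cg = CONTEXT_CODE[ContextLabel.CG]
        assert m.ctx_prob[0, cg, 0] == pytest.approx(1.0)  # C on motif '+'
        assert m.ctx_prob[1, cg, 1] == pytest.approx(1.0)  # G on motif '-'

    def test_no_cytosines_no_contexts(self):
        seq = "CCATATCC" + "CCTATACC"
        _, sm = self._matrix(seq, [(2, 6, "+"), (10, 14, "+")])
        m = build_motif_model(sm, pseudocount=0.0)
        assert (m.ctx_prob == 0).all()
        assert np.isnan(m.meth_mean).all()

    def test_pair_marginal_consistency_without_pseudocount(self, planted_model):
        sm = planted_model["matrix"]
        m = build_motif_model(sm, pseudocount=0.0)
        for i in range(m.length - 1):
            assert np.allclose(m.pair[i].sum(axis=1), m.p[i], atol=1e-9)
            assert np.allclose(m.pair[i].sum(axis=0), m.p[i + 1], atol=1e-9)

    def test_probability_normalization(self, planted_model):
        m = planted_model["motif"]
        assert np.allclose(m.p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(m.pair.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_context_probability_bounded_by_base_probability(self, planted_model):
        m = build_motif_model(planted_model["matrix"], pseudocount=0.0)
        for i in range(m.length):
            assert m.ctx_prob[i, :, 0].sum() <= m.p[i, BASES.index("C")] + 1e-9
            assert m.ctx_prob[i, :, 1].sum() <= m.p[i, BASES.index("G")] + 1e-9

    def test_meth_mean_present_only_with_contexts(self, planted_model):
        m = planted_model["motif"]
        has_m = ~np.isnan(m.meth_mean)
        assert (m.ctx_prob[has_m] > 0).all()


class TestBundle:
    def test_json_roundtrip(self, planted_model, tmp_path):
        bundle = planted_model["bundle"]
        path = tmp_path / "bg.json"
        bundle.save(path)
        back = BackgroundBundle.load(path)
        assert np.allclose(back.bg0.q, bundle.bg0.q, atol=1e-15)
        assert np.allclose(back.bg1.joint, bundle.bg1.joint, atol=1e-15)
        for ctx in ("CG", "CHG", "CHH"):
            assert back.mbg.prob(ContextLabel(ctx)) == pytest.approx(
                bundle.mbg.prob(ContextLabel(ctx))
            )

    def test_bg0_is_symmetrized_marginal_of_bg1(self, planted_model):
        bundle = planted_model["bundle"]
        m = bundle.bg1.marginal
        assert np.allclose(bundle.bg0.q, 0.5 * (m + m[::-1]), atol=1e-15)
        # close to the raw marginal (boundary terms only) and exactly
        # complement-symmetric
        assert np.allclose(bundle.bg0.q, m, atol=1e-3)
        assert np.allclose(bundle.bg0.q, bundle.bg0.q[::-1], atol=1e-16)

    def test_rerun_identical_json(self, planted_model, tmp_path):
        bundle = planted_model["bundle"]
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        bundle.save(p1)
        bundle.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
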