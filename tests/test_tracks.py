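import numpy as np
import pytest

from methylogo import (
    ContextLabel,
    FirstOrderBackground,
    MethylationBackground,
    MotifModel,
    ZeroOrderBackground,
    compute_tracks,
    dimer_track_heights,
    expected_methylation_line,
    kl2,
    methylation_track_heights,
    methylscape_profile,
    sequence_track_heights,
    total_information,
)
from methylogo.models import EPS
from methylogo.sites import CONTEXT_CODE
from oracles import (
    brute_force_relent,
    first_order_prob,
    random_first_order,
    random_motif,
    zero_order_prob,
)

CG = CONTEXT_CODE[ContextLabel.CG]
CHH = CONTEXT_CODE[ContextLabel.CHH]


def make_motif(p, pair=None, ctx_prob=None, meth_mean=None):
    p = np.asarray(p, dtype=float)
    L = p.shape[0]
    if pair is None:
        pair = np.einsum("ia,ib->iab", p[:-1], p[1:]) if L > 1 else np.zeros((0, 4, 4))
    if ctx_prob is None:
        ctx_prob = np.zeros((L, 3, 2))
    if meth_mean is None:
        meth_mean = np.full((L, 3, 2), np.nan)
    return MotifModel(p, np.asarray(pair, float), ctx_prob, meth_mean, n_sites=10)


def uniform_bg():
    return ZeroOrderBackground(np.full(4, 0.25))


def mbg(cg=0.8, chg=0.05, chh=0.02):
    return MethylationBackground(
        {ContextLabel.CG: cg, ContextLabel.CHG: chg, ContextLabel.CHH: chh}
    )


class TestSequenceTrack:
    def test_motif_equals_background_is_zero(self):
        q = np.array([0.4, 0.1, 0.1, 0.4])
        m = make_motif(np.tile(q, (3, 1)))
        h, _ = sequence_track_heights(m, ZeroOrderBackground(q))
        assert np.allclose(h, 0.0, atol=1e-12)

    def test_certain_base_uniform_background_two_bits(self):
        m = make_motif([[1.0, 0.0, 0.0, 0.0]])
        h, letters = sequence_track_heights(m, uniform_bg())
        assert h[0] == pytest.approx(2.0, abs=1e-12)
        assert letters[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_half_half_uniform_background_one_bit(self):
        m = make_motif([[0.5, 0.5, 0.0, 0.0]])
        h, letters = sequence_track_heights(m, uniform_bg())
        assert h[0] == pytest.approx(1.0, abs=1e-12)
        # relative letter height equals base frequency
        assert letters[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_letter_heights_sum_to_column(self):
        rng = np.random.default_rng(0)
        m = make_motif(random_motif(rng, 6))
        h, letters = sequence_track_heights(m, uniform_bg())
        assert np.allclose(letters.sum(axis=1), h, atol=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = make_motif(random_motif(rng, 4))
            q = rng.dirichlet(np.ones(4))
            h, _ = sequence_track_heights(m, ZeroOrderBackground(q))
            assert (h >= -1e-12).all()


class TestDimerTrack:
    def test_independent_background_all_zero(self):
        rng = np.random.default_rng(2)
        q = rng.dirichlet(np.ones(4))
        bg1 = FirstOrderBackground(np.outer(q, q))
        m = make_motif(random_motif(rng, 5))
        h, hi, lo = dimer_track_heights(m, bg1)
        assert np.allclose(h, 0.0, atol=1e-12)
        assert hi == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_five_fold_depleted_cg_single_term(self):
        # q uniform, q(C,G) = 0.0125 = 0.25*0.25/5; motif certain on CpG
        joint = np.full((4, 4), (1 - 0.0125) / 15)
        joint[1, 2] = 0.0125
        bg1 = FirstOrderBackground(joint)
        q0 = ZeroOrderBackground(np.full(4, 0.25))
        pair = np.zeros((1, 4, 4))
        pair[0, 1, 2] = 1.0
        m = make_motif([[0, 1, 0, 0], [0, 0, 1, 0]], pair=pair)
        h, _, _ = dimer_track_heights(m, bg1, q0)
        assert h[0] == pytest.approx(np.log2(5), abs=1e-12)

    def test_bars_within_theoretical_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            bg1 = FirstOrderBackground(random_first_order(rng))
            m = make_motif(random_motif(rng, 5))
            h, hi, lo = dimer_track_heights(m, bg1)
            assert (h <= hi + 1e-12).all()
            assert (h >= lo - 1e-12).all()


class TestOracleEquivalence:
    """The module's central check: track sums against exhaustive
    enumeration of all 4^L sequences."""

    @pytest.mark.parametrize("L", [1, 2, 3, 5])
    def test_sums_match_brute_force(self, L):
        rng = np.random.default_rng(100 + L)
        for _ in range(25):
            p = random_motif(rng, L)
            joint = random_first_order(rng)
            bg1 = FirstOrderBackground(joint)
            bg0 = bg1.marginal_zero_order()
            m = make_motif(p)
            seq_h, _ = sequence_track_heights(m, bg0)
            d0 = brute_force_relent(p, lambda s: zero_order_prob(s, bg0.q))
            assert seq_h.sum() == pytest.approx(d0, abs=1e-9)
            if L > 1:
                dim_h, _, _ = dimer_track_heights(m, bg1, bg0)
                d1 = brute_force_relent(p, lambda s: first_order_prob(s, joint))
                assert seq_h.sum() + dim_h.sum() == pytest.approx(d1, abs=1e-9)
                assert dim_h.sum() == pytest.approx(d1 - d0, abs=1e-9)

    def test_total_information_identity(self):
        rng = np.random.default_rng(200)
        p = random_motif(rng, 4)
        joint = random_first_order(rng)
        bg1 = FirstOrderBackground(joint)
        bg0 = bg1.marginal_zero_order()
        tracks = compute_tracks(make_motif(p), bg0, bg1, mbg())
        d1 = brute_force_relent(p, lambda s: first_order_prob(s, joint))
        assert total_information(tracks) == pytest.approx(d1, abs=1e-9)

    def test_all_zero_tracks(self):
        q = np.array([0.3, 0.2, 0.2, 0.3])
        bg1 = FirstOrderBackground(np.outer(q, q))
        bg0 = bg1.marginal_zero_order()
        p = np.tile(q, (4, 1))
        tracks = compute_tracks(make_motif(p), bg0, bg1, mbg())
        assert total_information(tracks) == pytest.approx(0.0, abs=1e-12)


class TestMethylationTrack:
    def _motif_with_meth(self, P, m, ctx=CG, strand=0, L=1):
        ctx_prob = np.zeros((L, 3, 2))
        meth = np.full((L, 3, 2), np.nan)
        ctx_prob[0, ctx, strand] = P
        meth[0, ctx, strand] = m
        p = np.tile([0.25, 0.25, 0.25, 0.25], (L, 1))
        return make_motif(p, ctx_prob=ctx_prob, meth_mean=meth)

    def test_methylation_equal_background_is_zero(self):
        m = self._motif_with_meth(P=0.7, m=0.8)
        comp = methylation_track_heights(m, mbg(cg=0.8))
        assert np.allclose(comp, 0.0, atol=1e-12)

    def test_no_contexts_is_zero(self):
        m = make_motif([[0.25, 0.25, 0.25, 0.25]])
        comp = methylation_track_heights(m, mbg())
        assert np.allclose(comp, 0.0)

    def test_saturated_cg_against_point_eight(self):
        m = self._motif_with_meth(P=1.0, m=1.0)
        comp = methylation_track_heights(m, mbg(cg=0.8))
        # epsilon-clamping perturbs the ideal lg(1/0.8) by ~1.4e-3
        assert comp[0, CG, 0] == pytest.approx(np.log2(1 / 0.8), abs=2e-3)
        assert comp[0, CG, 0] == pytest.approx(kl2(1.0, 0.8), abs=1e-15)

    def test_missing_mean_skipped_with_warning(self, caplog):
        ctx_prob = np.zeros((1, 3, 2))
        ctx_prob[0, CG, 0] = 0.5
        m = make_motif([[0.25, 0.25, 0.25, 0.25]], ctx_prob=ctx_prob)
        with caplog.at_level("WARNING"):
            comp = methylation_track_heights(m, mbg())
        assert comp[0, CG, 0] == 0.0
        assert "skipped" in caplog.text

    def test_monotone_in_distance_from_background(self):
        comps = [
            methylation_track_heights(
                self._motif_with_meth(P=0.6, m=lvl), mbg(cg=0.5)
            )[0, CG, 0]
            for lvl in (0.5, 0.6, 0.7, 0.85, 0.99)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(comps, comps[1:]))
        comps_down = [
            methylation_track_heights(
                self._motif_with_meth(P=0.6, m=lvl), mbg(cg=0.5)
            )[0, CG, 0]
            for lvl in (0.5, 0.4, 0.2, 0.01)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(comps_down, comps_down[1:]))

    def test_non_negative_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            ctx_prob = rng.dirichlet(np.ones(6)).reshape(3, 2)[None] * 0.5
            meth = rng.random((1, 3, 2))
            m = make_motif([[0.25] * 4], ctx_prob=ctx_prob, meth_mean=meth)
            comp = methylation_track_heights(m, mbg())
            assert (comp >= 0).all()


class TestExpectedMethylation:
    def test_single_context(self):
        ctx_prob = np.zeros((1, 3, 2))
        ctx_prob[0, CG, 0] = 0.4
        m = make_motif([[0.25] * 4], ctx_prob=ctx_prob)
        exp = expected_methylation_line(m, mbg(cg=0.8))
        assert exp[0, 0] == pytest.approx(0.8)
        assert np.isnan(exp[0, 1])

    def test_weighted_mean_of_contexts(self):
        ctx_prob = np.zeros((1, 3, 2))
        ctx_prob[0, CG, 0] = 0.6
        ctx_prob[0, CHH, 0] = 0.4
        m = make_motif([[0.25] * 4], ctx_prob=ctx_prob)
        exp = expected_methylation_line(m, mbg(cg=0.8, chh=0.02))
        assert exp[0, 0] == pytest.approx(0.6 * 0.8 + 0.4 * 0.02, abs=1e-12)

    def test_undefined_without_cytosines(self):
        m = make_motif([[0.25] * 4])
        assert np.isnan(expected_methylation_line(m, mbg())).all()


class TestReverseComplementSymmetry:
    def test_tracks_mirror_exactly(self, planted_model):
        """All three tracks computed on the reverse-complemented sites
        mirror the originals with (ctx, +) <-> (ctx, -) swapped."""
        from methylogo import build_motif_model

        bundle = planted_model["bundle"]
        sm = planted_model["matrix"]
        fwd = compute_tracks(
            build_motif_model(sm), bundle.bg0, bundle.bg1, bundle.mbg
        )
        rev = compute_tracks(
            build_motif_model(sm.reverse_complement()),
            bundle.bg0, bundle.bg1, bundle.mbg,
        )
        assert np.allclose(rev.seq_heights, fwd.seq_heights[::-1], atol=1e-12)
        assert np.allclose(rev.dimer_heights, fwd.dimer_heights[::-1], atol=1e-12)
        assert np.allclose(
            rev.meth_components, fwd.meth_components[::-1, :, ::-1], atol=1e-12
        )
        assert np.allclose(
            rev.expected_meth, fwd.expected_meth[::-1, ::-1],
            atol=1e-12, equal_nan=True,
        )


class TestScapeProfile:
    def test_window_exceeding_flank_is_error(self, planted_model):
        with pytest.raises(ValueError, match="flank"):
            methylscape_profile(planted_model["matrix"], mbg(), window=99)

    def test_null_flanks_near_zero_entropy(self, planted_model):
        """Flank methylation equals the background, so flank entropy is
        sampling noise while the hypo-methylated core CG peaks inside."""
        bundle = planted_model["bundle"]
        sm = planted_model["matrix"]
        prof = methylscape_profile(sm, bundle.mbg, window=8)
        core = (prof.offsets >= 0) & (prof.offsets < prof.motif_length)
        flank_cg = prof.entropy[CG][~core]
        assert np.nanmax(flank_cg, initial=0.0) < 0.2
        peak_off = prof.offsets[int(np.argmax(prof.entropy[CG]))]
        assert 0 <= peak_off < prof.motif_length

    def test_zero_where_context_absent(self, planted_model):
        prof = methylscape_profile(planted_model["matrix"], mbg(), window=5)
        absent = prof.ctx_prob == 0
        assert np.allclose(prof.entropy[absent], 0.0)

    def test_entropy_weighting_flag(self, planted_model):
        bundle = planted_model["bundle"]
        sm = planted_model["matrix"]
        w = methylscape_profile(sm, bundle.mbg, window=4, weighted=True)
        u = methylscape_profile(sm, bundle.mbg, window=4, weighted=False)
        mask = w.ctx_prob > 0
        assert np.allclose(
            w.entropy[mask], (u.entropy * w.ctx_prob)[mask], atol=1e-12
        )

    def test_tsv_schema(self, planted_model, tmp_path):
        import pandas as pd

        bundle = planted_model["bundle"]
        prof = methylscape_profile(planted_model["matrix"], bundle.mbg, window=4)
        path = tmp_path / "scape.tsv"
        prof.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns)[0] == "offset"
        assert len(df) == len(prof.offsets)
        assert df["entropy_CG"].min() >= 0.0
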