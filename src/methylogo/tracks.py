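"""Relative-entropy track heights for methylation-aware sequence logos.

All heights are in bits (base-2 logarithms).  Three tracks share one
currency so that total information can be read off a figure by adding
column heights:

sequence track
    seq_heights[i] = sum_b p_i(b) lg(p_i(b) / q(b)) — the per-position KL
    divergence of the motif base distribution from the zero-order
    background; letters within a column are scaled by p_i(b).

dimer track
    The difference between the motif's relative entropy against a
    first-order background and against the zero-order background
    decomposes into one term per adjacent position pair when the
    zero-order model is the marginal of the first-order joint:
    dimer_heights[j] = sum_{a,b} p_{j,j+1}(a,b) lg(q(a) q(b) / q(a,b)).
    Positive bars mark motifs using background-under-represented dimers
    (CpG, classically); negative bars mark over-represented ones.

methylation track
    meth_components[i][(ctx, s)] = P(ctx, s | i) * KL2(m_{i,ctx,s} ||
    m_bg(ctx)) over the six strand-specific contexts (CG/CHG/CHH x two
    strands); KL2 is the binary KL divergence between Bernoulli
    methylation probabilities.  The multiplicative context-probability
    term keeps rare contexts from dominating a column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import CONTEXTS
from .models import (
    EPS,
    BASES,
    FirstOrderBackground,
    MethylationBackground,
    MotifModel,
    ZeroOrderBackground,
)
from .sites import CONTEXT_CODE, SiteMatrix
from .genome import ContextLabel

log = logging.getLogger(__name__)

__all__ = [
    "TrackSet",
    "ScapeProfile",
    "kl2",
    "sequence_track_heights",
    "dimer_track_heights",
    "methylation_track_heights",
    "expected_methylation_line",
    "observed_methylation",
    "compute_tracks",
    "total_information",
    "methylscape_profile",
]


def kl2(p: float, q: float) -> float:
    """Binary KL divergence p·lg(p/q) + (1−p)·lg((1−p)/(1−q)) in bits.

    Both arguments are clamped into [EPS, 1−EPS] so saturated methylation
    levels yield finite heights.
    """
    p = min(max(p, EPS), 1.0 - EPS)
    q = min(max(q, EPS), 1.0 - EPS)
    return p * np.log2(p / q) + (1.0 - p) * np.log2((1.0 - p) / (1.0 - q))


def sequence_track_heights(
    motif: MotifModel, bg0: ZeroOrderBackground
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column KL heights and per-letter heights (p_i(b) x column).

    Zero motif probabilities contribute nothing (0·lg 0 = 0).
    """
    p = motif.p
    q = bg0.q[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
    heights = terms.sum(axis=1)
    letters = p * heights[:, None]
    return heights, letters


def dimer_track_heights(
    motif: MotifModel,
    bg1: FirstOrderBackground,
    bg0: ZeroOrderBackground | None = None,
) -> tuple[np.ndarray, float, float]:
    """Signed bar heights between adjacent columns, plus theoretical bounds.

    ``bg0`` defaults to the marginal of ``bg1`` — the pairing under which
    the bars sum exactly to D(M||B1) − D(M||B0).  The bounds are the
    extrema of lg(q(a) q(b) / q(a,b)) over the 16 ordered pairs: no motif
    can place a bar outside them.
    """
    if bg0 is None:
        bg0 = bg1.marginal_zero_order()
    q0 = bg0.q
    logratio = np.log2(np.outer(q0, q0) / bg1.joint)  # (4, 4)
    heights = np.array(
        [float((motif.pair[j] * logratio).sum()) for j in range(motif.length - 1)]
    )
    return heights, float(logratio.max()), float(logratio.min())


def methylation_track_heights(
    motif: MotifModel, mbg: MethylationBackground
) -> np.ndarray:
    """Per-position (3 contexts x 2 strands) methylation information, bits.

    A class with cytosines but no surviving methylation observation is
    skipped with a warning (its height cannot be estimated).
    """
    L = motif.length
    comp = np.zeros((L, 3, 2))
    for i in range(L):
        for ctx in CONTEXTS:
            c = CONTEXT_CODE[ctx]
            for s in range(2):
                P = motif.ctx_prob[i, c, s]
                if P <= 0:
                    continue
                m = motif.meth_mean[i, c, s]
                if np.isnan(m):
                    log.warning(
                        "position %d (%s, %s): cytosines present but no "
                        "methylation observation; component skipped",
                        i, ctx, "+-"[s],
                    )
                    continue
                comp[i, c, s] = P * kl2(m, mbg.prob(ctx))
    return comp


def expected_methylation_line(
    motif: MotifModel, mbg: MethylationBackground
) -> np.ndarray:
    """Background-expected methylation per position and strand.

    expected[i, s] = sum_ctx P(ctx,s|i) m_bg(ctx) / sum_ctx P(ctx,s|i);
    NaN where the position carries no strand-s cytosine.
    """
    out = np.full((motif.length, 2), np.nan)
    mbgv = np.array([mbg.prob(ctx) for ctx in CONTEXTS])
    for i in range(motif.length):
        for s in range(2):
            P = motif.ctx_prob[i, :, s]
            tot = P.sum()
            if tot > 0:
                out[i, s] = float((P * mbgv).sum() / tot)
    return out


def observed_methylation(motif: MotifModel) -> np.ndarray:
    """Mean observed methylation per position and strand (drives glyph
    shading); NaN where no class has an observation."""
    out = np.full((motif.length, 2), np.nan)
    for i in range(motif.length):
        for s in range(2):
            P = motif.ctx_prob[i, :, s]
            m = motif.meth_mean[i, :, s]
            ok = (P > 0) & ~np.isnan(m)
            if ok.any():
                out[i, s] = float((P[ok] * m[ok]).sum() / P[ok].sum())
    return out


@dataclass
class TrackSet:
    """All computed heights for one logo, in bits."""

    seq_heights: np.ndarray  # (L,)
    letter_heights: np.ndarray  # (L, 4) in BASES order
    dimer_heights: np.ndarray  # (L-1,), signed
    dimer_bound_max: float
    dimer_bound_min: float
    meth_components: np.ndarray  # (L, 3, 2), non-negative
    expected_meth: np.ndarray  # (L, 2), NaN where undefined
    observed_meth: np.ndarray  # (L, 2), NaN where undefined

    @property
    def length(self) -> int:
        return len(self.seq_heights)

    def meth_column_heights(self) -> np.ndarray:
        return self.meth_components.sum(axis=(1, 2))

    def to_tsv(self, path) -> None:
        """One row per position; dimer bar j is reported at position j
        (between columns j and j+1, NaN on the last row)."""
        import pandas as pd

        L = self.length
        cols: dict[str, list] = {"position": list(range(L))}
        cols["seq_height_bits"] = list(self.seq_heights)
        for k, b in enumerate(BASES):
            cols[f"letter_{b}"] = list(self.letter_heights[:, k])
        dim = list(self.dimer_heights) + [np.nan]
        cols["dimer_height_bits"] = dim[:L]
        for ctx in CONTEXTS:
            c = CONTEXT_CODE[ctx]
            for s, sym in enumerate("+-"):
                cols[f"meth_{ctx}_{sym}"] = list(self.meth_components[:, c, s])
        for s, sym in enumerate("+-"):
            cols[f"expected_meth_{sym}"] = list(self.expected_meth[:, s])
            cols[f"observed_meth_{sym}"] = list(self.observed_meth[:, s])
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_tracks(
    motif: MotifModel,
    bg0: ZeroOrderBackground,
    bg1: FirstOrderBackground,
    mbg: MethylationBackground,
) -> TrackSet:
    """Convenience: compute every track for one motif/background pairing."""
    seq, letters = sequence_track_heights(motif, bg0)
    dimers, dmax, dmin = dimer_track_heights(motif, bg1, bg0)
    return TrackSet(
        seq_heights=seq,
        letter_heights=letters,
        dimer_heights=dimers,
        dimer_bound_max=dmax,
        dimer_bound_min=dmin,
        meth_components=methylation_track_heights(motif, mbg),
        expected_meth=expected_methylation_line(motif, mbg),
        observed_meth=observed_methylation(motif),
    )


def total_information(tracks: TrackSet) -> float:
    """Sum of all column heights across the three tracks, in bits."""
    return float(
        tracks.seq_heights.sum()
        + tracks.dimer_heights.sum()
        + tracks.meth_components.sum()
    )


@dataclass
class ScapeProfile:
    """Context probability, methylation and methylation relative entropy
    per offset in a window around the motif (both strands pooled)."""

    offsets: np.ndarray  # motif-relative offsets, core is 0 .. L-1
    motif_length: int
    ctx_prob: np.ndarray  # (3, n_offsets)
    meth: np.ndarray  # (3, n_offsets), NaN where no observation
    entropy: np.ndarray  # (3, n_offsets), bits, 0 where ctx_prob = 0
    m_bg: dict = field(default_factory=dict)  # per-context background level
    weighted: bool = True

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols: dict[str, list] = {"offset": list(self.offsets)}
        for ctx in CONTEXTS:
            c = CONTEXT_CODE[ctx]
            cols[f"ctx_prob_{ctx}"] = list(self.ctx_prob[c])
            cols[f"meth_{ctx}"] = list(self.meth[c])
            cols[f"entropy_{ctx}"] = list(self.entropy[c])
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def methylscape_profile(
    sites: SiteMatrix,
    mbg: MethylationBackground,
    window: int = 500,
    weighted: bool = True,
) -> ScapeProfile:
    """Per-offset context probability, mean methylation and methylation
    relative entropy over ``[-window, L + window)`` around the motif.

    Strands are pooled after motif orientation.  The entropy row is
    P_ctx-weighted binary KL by default (the same quantity the
    methylation track stacks per column); ``weighted=False`` reports the
    unweighted KL wherever the context occurs.
    """
    if window > sites.flank:
        raise ValueError(
            f"window {window} exceeds available flank {sites.flank}"
        )
    lo = sites.flank - window
    hi = sites.flank + sites.motif_length + window
    offsets = np.arange(lo, hi) - sites.flank
    n_off = hi - lo
    undef = CONTEXT_CODE[ContextLabel.UNDEFINED]

    ctx_prob = np.zeros((3, n_off))
    meth = np.full((3, n_off), np.nan)
    entropy = np.zeros((3, n_off))
    for k, j in enumerate(range(lo, hi)):
        col_ctx = sites.contexts[:, j]
        col_lvl = sites.levels[:, j]
        denom = int((col_ctx != undef).sum())
        if denom == 0:
            continue
        for ctx in CONTEXTS:
            c = CONTEXT_CODE[ctx]
            mask = col_ctx == c
            P = float(mask.sum()) / denom
            ctx_prob[c, k] = P
            if P == 0:
                continue
            lvls = col_lvl[mask]
            lvls = lvls[~np.isnan(lvls)]
            if lvls.size == 0:
                continue
            m = float(lvls.mean())
            meth[c, k] = m
            kl = kl2(m, mbg.prob(ctx))
            entropy[c, k] = P * kl if weighted else kl
    return ScapeProfile(
        offsets=offsets,
        motif_length=sites.motif_length,
        ctx_prob=ctx_prob,
        meth=meth,
        entropy=entropy,
        m_bg={str(ctx): mbg.prob(ctx) for ctx in CONTEXTS},
        weighted=weighted,
    )
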