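"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own decompositions: relative
entropies are computed by exhaustive enumeration of all 4^L sequences,
interval intersection by O(n*m) pairwise checks, and context counting by
a direct trinucleotide scan.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def enumerate_seqs(L: int):
    return itertools.product(range(4), repeat=L)


def motif_prob(seq, p: np.ndarray) -> float:
    """P(seq | independent-position motif model), seq as base indices."""
    out = 1.0
    for i, b in enumerate(seq):
        out *= p[i, b]
    return out


def zero_order_prob(seq, q: np.ndarray) -> float:
    out = 1.0
    for b in seq:
        out *= q[b]
    return out


def first_order_prob(seq, joint: np.ndarray) -> float:
    """P(seq | first-order chain): first base from the left marginal of
    the joint, then conditionals q(b|a) = joint[a,b] / marginal[a]."""
    marg = joint.sum(axis=1)
    cond = joint / marg[:, None]
    out = marg[seq[0]]
    for a, b in zip(seq, seq[1:]):
        out *= cond[a, b]
    return out


def brute_force_relent(p: np.ndarray, bg_prob_fn) -> float:
    """D(M || B) in bits by summing over every length-L sequence."""
    L = p.shape[0]
    total = 0.0
    for seq in enumerate_seqs(L):
        w = motif_prob(seq, p)
        if w == 0.0:
            continue
        total += w * np.log2(w / bg_prob_fn(seq))
    return total


def naive_intersect(a, b, mode: str):
    """O(n*m) reference for interval filtering (half-open coordinates)."""
    kept = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            if mode == "overlap-any":
                if ra.start < rb.end and rb.start < ra.end:
                    kept.append(ra)
                    break
            else:
                if rb.start <= ra.start and ra.end <= rb.end:
                    kept.append(ra)
                    break
    return kept


def scan_contexts(seq: str):
    """Context of every cytosine on both strands of ``seq`` by direct
    trinucleotide inspection; cytosines whose downstream bases run off
    the end are skipped (UNDEFINED)."""
    out = {}  # (pos, strand) -> 'CG' | 'CHG' | 'CHH'
    n = len(seq)
    for i, c in enumerate(seq):
        if c == "C":
            if i + 1 >= n:
                continue
            if seq[i + 1] == "G":
                out[(i, "+")] = "CG"
            elif i + 2 < n:
                out[(i, "+")] = "CHG" if seq[i + 2] == "G" else "CHH"
        if c == "G":
            if i - 1 < 0:
                continue
            if seq[i - 1] == "C":
                out[(i, "-")] = "CG"
            elif i - 2 >= 0:
                out[(i, "-")] = "CHG" if seq[i - 2] == "C" else "CHH"
    return out


def symmetrized_chain_joint(T) -> tuple[np.ndarray, np.ndarray]:
    """Stationary distribution and the double-strand dimer joint of a
    first-order chain with transition matrix T (ACGT order).

    Counting dimers on both strands pools J(a,b) = pi(a) T(a,b) with its
    reverse complement J(rc(b), rc(a)); complementing a base index is
    reversal in ACGT order.
    """
    T = np.asarray(T, dtype=float)
    evals, evecs = np.linalg.eig(T.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = pi / pi.sum()
    J = pi[:, None] * T
    J_rc = J[::-1, ::-1].T
    return pi, 0.5 * (J + J_rc)


def random_motif(rng: np.random.Generator, L: int) -> np.ndarray:
    p = rng.dirichlet(np.ones(4), size=L)
    return p


def random_first_order(rng: np.random.Generator) -> np.ndarray:
    joint = rng.dirichlet(np.ones(16)).reshape(4, 4)
    return joint
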