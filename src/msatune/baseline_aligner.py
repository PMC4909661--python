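"""A self-contained progressive multiple aligner.

Purpose: give the parameter sweep an aligner that honours the same three
knobs as production tools — substitution matrix, gap-open penalty (GOP) and
gap-extension penalty (GEP) — without any external binary. It is a minimal
progressive method (k-mer guide tree + profile-profile alignment), not an
emulation of any particular production aligner.

Gap model: a gap of length L costs ``gop + gep*(L-1)``; terminal gaps are
penalised like internal ones. Profile columns are scored by the expected
substitution score under the product of the two columns' residue-frequency
vectors; gap fractions contribute nothing to the substitution term and are
charged only through the affine gap states.

Determinism: on equal dynamic-programming scores the traceback prefers
match/mismatch, then a gap in the second profile, then a gap in the first;
guide-tree distance ties are broken on the lexicographically smallest pair
of cluster labels (a cluster is labelled by its smallest member id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TSequence

import numpy as np
from numba import njit

from .errors import MsatuneError
from .msa_io import Alignment, Sequence
from .submat import SubstitutionMatrix

# DP states / traceback codes
_M, _X, _Y = 0, 1, 2  # match, gap-in-second (consume first), gap-in-first
_NEG = -1e30


@njit(cache=False)
def _gotoh(score_mat, gop, gep):  # pragma: no cover - exercised via wrapper
    """Affine-gap global alignment over a precomputed column-score matrix.

    Returns (best_score, tb) where tb[s, i, j] is the predecessor state of
    state s at cell (i, j). State preference on ties: M, then X, then Y.
    """
    n, m = score_mat.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    tb = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gop + gep * (i - 1))
        tb[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gop + gep * (j - 1))
        tb[2, 0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_mat[i - 1, j - 1]
            # M: from any state diagonally; prefer M >= X >= Y on ties
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + s
            tb[0, i, j] = arg
            # X: consume row i of first profile against a gap. A gap may
            # open from M or directly after a Y gap (two adjacent opposite
            # gaps can beat one costly mismatch), so all transitions are
            # allowed; extension from X costs gep only.
            bx, ax = M[i - 1, j] - gop, 0
            if X[i - 1, j] - gep > bx:
                bx, ax = X[i - 1, j] - gep, 1
            if Y[i - 1, j] - gop > bx:
                bx, ax = Y[i - 1, j] - gop, 2
            X[i, j] = bx
            tb[1, i, j] = ax
            # Y: consume column j of second profile against a gap
            by, ay = M[i, j - 1] - gop, 0
            if X[i, j - 1] - gop > by:
                by, ay = X[i, j - 1] - gop, 1
            if Y[i, j - 1] - gep > by:
                by, ay = Y[i, j - 1] - gep, 2
            Y[i, j] = by
            tb[2, i, j] = ay
    best, state = M[n, m], 0
    if X[n, m] > best:
        best, state = X[n, m], 1
    if Y[n, m] > best:
        best, state = Y[n, m], 2
    return best, state, tb


def _traceback(state: int, tb: np.ndarray, n: int, m: int) -> list[tuple[int, int]]:
    """Recover the aligned column path as (i, j) moves; -1 marks a gap."""
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = tb[state, i, j]
        if state == _M:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _X:
            path.append((i - 1, -1))
            i -= 1
        else:
            path.append((-1, j - 1))
            j -= 1
        state = prev
    path.reverse()
    return path


@dataclass
class Profile:
    """An alignment plus per-column residue frequencies (gap included)."""

    alignment: Alignment
    freqs: np.ndarray  # (n_cols, n_letters) residue frequencies
    gap_freq: np.ndarray  # (n_cols,)


def _letter_index(matrix: SubstitutionMatrix) -> tuple[dict, np.ndarray]:
    letters = sorted(matrix.alphabet - {"*"})
    idx = {c: i for i, c in enumerate(letters)}
    S = np.array(
        [[matrix.scores[(a, b)] for b in letters] for a in letters],
        dtype=np.float64,
    )
    return idx, S


def _profile_from_alignment(aln: Alignment, idx: dict) -> Profile:
    nL = len(idx)
    freqs = np.zeros((aln.n_cols, nL))
    gaps = np.zeros(aln.n_cols)
    for _, gapped in aln.rows:
        for j, c in enumerate(gapped):
            if c == "-":
                gaps[j] += 1
            else:
                freqs[j, idx.get(c, idx["X"])] += 1
    n = aln.n_rows
    return Profile(aln, freqs / n, gaps / n)


def _merge(p1: Profile, p2: Profile, S: np.ndarray, idx: dict,
           gop: float, gep: float) -> Profile:
    score_mat = p1.freqs @ S @ p2.freqs.T
    best, state, tb = _gotoh(score_mat, float(gop), float(gep))
    path = _traceback(state, tb, p1.alignment.n_cols, p2.alignment.n_cols)
    rows = []
    for rid, gapped in p1.alignment.rows:
        rows.append((rid, "".join(gapped[i] if i >= 0 else "-" for i, _ in path)))
    for rid, gapped in p2.alignment.rows:
        rows.append((rid, "".join(gapped[j] if j >= 0 else "-" for _, j in path)))
    return _profile_from_alignment(Alignment(rows), idx)


def pairwise_score(a: Sequence, b: Sequence, m: SubstitutionMatrix,
                   gop: float, gep: float) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    idx, S = _letter_index(m)
    ia = np.array([idx.get(c, idx["X"]) for c in a.residues])
    ib = np.array([idx.get(c, idx["X"]) for c in b.residues])
    score_mat = S[np.ix_(ia, ib)]
    best, _, _ = _gotoh(score_mat, float(gop), float(gep))
    return float(best)


def pairwise_align(a: Sequence, b: Sequence, m: SubstitutionMatrix,
                   gop: float, gep: float) -> Alignment:
    """Globally align two sequences with affine gap costs."""
    if gop < 0 or gep < 0:
        raise MsatuneError("gap penalties must be non-negative")
    idx, S = _letter_index(m)
    p1 = _profile_from_alignment(Alignment([(a.id, a.residues)]), idx)
    p2 = _profile_from_alignment(Alignment([(b.id, b.residues)]), idx)
    return _merge(p1, p2, S, idx, gop, gep).alignment


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

@dataclass
class GuideTree:
    """Rooted strictly-binary tree; leaves carry sequence ids."""

    leaf: Optional[str] = None
    left: Optional["GuideTree"] = None
    right: Optional["GuideTree"] = None

    def leaves(self) -> list[str]:
        if self.leaf is not None:
            return [self.leaf]
        return self.left.leaves() + self.right.leaves()


def kmer_distance(a: Sequence, b: Sequence, k: int = 3) -> float:
    """1 minus the shared k-mer fraction (normalised by the smaller set)."""
    kk = min(k, len(a), len(b))
    ka = {a.residues[i : i + kk] for i in range(len(a) - kk + 1)}
    kb = {b.residues[i : i + kk] for i in range(len(b) - kk + 1)}
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def upgma(dist: np.ndarray, labels: TSequence[str]) -> GuideTree:
    """Average-linkage (UPGMA) clustering with deterministic tie-breaks.

    Ties in the minimum distance are broken on the lexicographically
    smallest (min-label, min-label) pair of the candidate clusters.
    """
    dist = np.asarray(dist, dtype=float)
    clusters = {i: GuideTree(leaf=lab) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in clusters}
    minlab = {i: lab for i, lab in enumerate(labels)}
    d = {
        (i, j): dist[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                *sorted((minlab[kv[0][0]], minlab[kv[0][1]])),
            ),
        )[0]
        i, j = best
        node = GuideTree(left=clusters[i], right=clusters[j])
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(new, k), max(new, k))] = (ni * dik + nj * djk) / (ni + nj)
        del d[(i, j)]
        for x in (i, j):
            del clusters[x], sizes[x]
        clusters[new] = node
        sizes[new] = ni + nj
        minlab[new] = min(minlab[i], minlab[j])
    return next(iter(clusters.values()))


def build_guide_tree(seqs: TSequence[Sequence]) -> GuideTree:
    """UPGMA tree over pairwise 3-mer distances."""
    if len(seqs) < 2:
        raise MsatuneError("need at least 2 sequences for a guide tree")
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(seqs[i], seqs[j])
    return upgma(dist, [s.id for s in seqs])


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def progressive_align(seqs: TSequence[Sequence], m: SubstitutionMatrix,
                      gop: float, gep: float) -> Alignment:
    """Align ``seqs`` progressively along a UPGMA guide tree.

    Output rows are returned in input order; every row ungaps to its input
    sequence exactly.
    """
    if len(seqs) < 2:
        raise MsatuneError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise MsatuneError("duplicate sequence ids")
    by_id = {s.id: s for s in seqs}
    tree = build_guide_tree(seqs)
    idx, S = _letter_index(m)

    def align_node(node: GuideTree) -> Profile:
        if node.leaf is not None:
            s = by_id[node.leaf]
            return _profile_from_alignment(Alignment([(s.id, s.residues)]), idx)
        return _merge(align_node(node.left), align_node(node.right), S, idx,
                      gop, gep)

    merged = align_node(tree).alignment
    order = {rid: i for i, rid in enumerate(ids)}
    rows = sorted(merged.rows, key=lambda r: order[r[0]])
    return Alignment(rows)
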