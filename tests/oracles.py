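"""Independent brute-force oracles used only by the tests.

These deliberately re-derive every quantity from first principles —
double sums over ordered residue pairs, exhaustive alignment enumeration,
one-pass argmax scans — so they share no code path with the package.
"""

from fractions import Fraction
from itertools import combinations

from msatune.msa_io import Alignment, ReferenceAlignment


def _keys_by_column(aln: Alignment):
    """Residue keys (row_id, 1-based ungapped position) per column."""
    cols = [[] for _ in range(aln.n_cols)]
    for rid, gapped in aln.rows:
        pos = 0
        for j, c in enumerate(gapped):
            if c != "-":
                pos += 1
                cols[j].append((rid, pos))
    return cols


def sps_oracle(test: Alignment, ref: ReferenceAlignment, ordered: bool = True):
    """Sum-of-pairs score straight from the defining double sum.

    Returns (Fraction score, numerator, denominator) counting ordered
    residue pairs (j != k) when ``ordered`` else unordered pairs.
    """
    mask = ref.core_mask
    ref_cols = _keys_by_column(ref.alignment)
    aligned = set()
    denominator = 0
    for j, keys in enumerate(ref_cols):
        if mask is not None and not mask[j]:
            continue
        for a in keys:
            for b in keys:
                if a != b:
                    aligned.add((a, b))
                    denominator += 1
    numerator = 0
    for keys in _keys_by_column(test):
        for a in keys:
            for b in keys:
                if a != b and (a, b) in aligned:
                    numerator += 1
    if not ordered:
        numerator //= 2
        denominator //= 2
    return Fraction(numerator, denominator), numerator, denominator


def cs_oracle(test: Alignment, ref: ReferenceAlignment,
              ignore_single: bool = False) -> Fraction:
    """Column score by direct column-content comparison."""
    mask = ref.core_mask
    ref_contents = [
        frozenset(keys)
        for j, keys in enumerate(_keys_by_column(ref.alignment))
        if keys and (mask is None or mask[j])
    ]
    if ignore_single:
        ref_contents = [c for c in ref_contents if len(c) > 1]
    test_contents = {frozenset(k) for k in _keys_by_column(test) if k}
    return Fraction(
        sum(1 for c in ref_contents if c in test_contents), len(ref_contents)
    )


# ---------------------------------------------------------------------------
# Exhaustive pairwise-alignment oracle
# ---------------------------------------------------------------------------

def enumerate_alignments(la: int, lb: int):
    """All global alignments of sequences of lengths la, lb as lists of
    (i, j) column pairs with -1 marking a gap. No gap-gap columns."""
    def rec(i, j):
        if i == la and j == lb:
            yield []
            return
        if i < la and j < lb:
            for rest in rec(i + 1, j + 1):
                yield [(i, j)] + rest
        if i < la:
            for rest in rec(i + 1, j):
                yield [(i, -1)] + rest
        if j < lb:
            for rest in rec(i, j + 1):
                yield [(-1, j)] + rest

    yield from rec(0, 0)


def _gap_cost(flags, gop, gep):
    cost = 0.0
    run = 0
    for is_gap in flags:
        if is_gap:
            run += 1
        else:
            if run:
                cost += gop + gep * (run - 1)
            run = 0
    if run:
        cost += gop + gep * (run - 1)
    return cost


def best_pairwise_score(a: str, b: str, matrix, gop: float, gep: float) -> float:
    """Maximum of sum(pair scores) - sum(affine gap costs) over every
    possible global alignment (terminal gaps charged like internal ones)."""
    best = None
    for cols in enumerate_alignments(len(a), len(b)):
        score = 0.0
        for i, j in cols:
            if i >= 0 and j >= 0:
                score += matrix.score(a[i], b[j])
        score -= _gap_cost([i < 0 for i, _ in cols], gop, gep)
        score -= _gap_cost([j < 0 for _, j in cols], gop, gep)
        if best is None or score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# One-pass aggregation oracle
# ---------------------------------------------------------------------------

def bruteforce_optimum(records, matrix_order):
    """From raw sweep records, the best (matrix, gop, gep) per dataset by
    mean SPS over OK cells: single linear scan, deterministic tie-breaks
    (smallest gop, then gep, then matrix order)."""
    sums: dict = {}
    for r in records:
        if r["status"] != "OK":
            continue
        key = (r["dataset_id"], r["matrix"], r["gop"], r["gep"])
        s, n = sums.get(key, (0.0, 0))
        sums[key] = (s + r["sps"], n + 1)
    rank = {m: i for i, m in enumerate(matrix_order)}
    best: dict = {}
    for (ds, m, gop, gep), (s, n) in sums.items():
        mean = s / n
        cand = (-mean, rank.get(m, len(rank)), gop, gep)
        if ds not in best or cand < best[ds][0]:
            best[ds] = (cand, {"dataset_id": ds, "matrix": m, "gop": gop,
                               "gep": gep, "mean_sps": mean})
    return {ds: v for ds, (_, v) in best.items()}
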