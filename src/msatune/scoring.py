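"""Reference-based alignment accuracy scores.

Two standard metrics compare a test alignment against a curated reference:

* **SPS** (sum-of-pairs score): the fraction of residue pairs that the
  reference places in a common column which the test alignment also places
  in a common column. Writing ``p_ijk = 1`` when the residues in rows *j*
  and *k* of test column *i* are aligned in the reference, the column score
  is ``S_i = Σ_j Σ_{k≠j} p_ijk`` and ``SPS = Σ_i S_i / Σ_i S_ri``, where
  ``S_ri`` is the same quantity evaluated on the reference's own columns.
  The double sum runs over ordered pairs; both numerator and denominator
  carry the same factor of two, so the implementation counts unordered
  pairs (a property test asserts the equivalence).

* **CS** (column score): the fraction of scored reference columns whose
  full residue content is reproduced as the content of a single test
  column.

Residue identity is positional: a residue is keyed by (row id, 1-based
position in the ungapped row), never by its letter, so repeated letters
cannot produce spurious matches. When the reference carries a core-column
mask, only masked columns define pairs (standard practice for benchmarks
annotated with reliably-aligned core blocks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .errors import InputMismatchError, ScoringError
from .msa_io import Alignment, CaseBundle, ReferenceAlignment, load_case

logger = logging.getLogger(__name__)

#: (row_id, 1-based ungapped position) — identifies a residue independently
#: of which column an alignment currently places it in.
ResidueKey = tuple[str, int]


@dataclass
class PairIndex:
    """The set of reference-aligned residue pairs (unordered)."""

    pairs: set[frozenset]
    denominator_total: int
    column_contents: list[frozenset]  # per scored reference column


@dataclass
class ScoreResult:
    sps: float
    cs: float
    numerator: int
    denominator: int
    n_ref_columns_scored: int


def _column_keys(aln: Alignment) -> list[list[ResidueKey]]:
    """Per column, the residue keys of its non-gap cells (row order)."""
    cols: list[list[ResidueKey]] = [[] for _ in range(aln.n_cols)]
    for rid, gapped in aln.rows:
        pos = 0
        for j, c in enumerate(gapped):
            if c != "-":
                pos += 1
                cols[j].append((rid, pos))
    return cols


def build_pair_index(ref: ReferenceAlignment, *, use_core_mask: bool = True) -> PairIndex:
    """Enumerate every unordered residue pair co-occupying a scored
    reference column."""
    aln = ref.alignment
    if aln.n_rows < 2:
        raise ScoringError("reference needs at least 2 rows")
    mask = ref.core_mask if (use_core_mask and ref.core_mask is not None) else None
    pairs: set[frozenset] = set()
    contents: list[frozenset] = []
    for j, keys in enumerate(_column_keys(aln)):
        if mask is not None and not mask[j]:
            continue
        if keys:
            contents.append(frozenset(keys))
        for a, b in combinations(keys, 2):
            pairs.add(frozenset((a, b)))
    if not pairs:
        raise ScoringError("reference defines no aligned pairs")
    return PairIndex(pairs, len(pairs), contents)


def _check_same_content(test: Alignment, ref: Alignment) -> None:
    if set(test.ids) != set(ref.ids):
        only_t = sorted(set(test.ids) - set(ref.ids))
        only_r = sorted(set(ref.ids) - set(test.ids))
        raise InputMismatchError(
            f"row-id mismatch: only in test {only_t}, only in reference {only_r}"
        )
    for rid in ref.ids:
        if test.ungapped(rid).upper() != ref.ungapped(rid).upper():
            raise InputMismatchError(
                f"row {rid!r}: ungapped sequence differs between test and reference"
            )


def sps(
    test: Alignment,
    ref: ReferenceAlignment,
    *,
    use_core_mask: bool = True,
    cs_ignore_single_residue_columns: bool = False,
) -> ScoreResult:
    """Score ``test`` against ``ref``; returns SPS and CS together."""
    _check_same_content(test, ref.alignment)
    index = build_pair_index(ref, use_core_mask=use_core_mask)
    test_cols = _column_keys(test)
    numerator = 0
    test_contents = set()
    for keys in test_cols:
        if keys:
            test_contents.add(frozenset(keys))
        for a, b in combinations(keys, 2):
            if frozenset((a, b)) in index.pairs:
                numerator += 1
    ref_cols = index.column_contents
    if cs_ignore_single_residue_columns:
        ref_cols = [c for c in ref_cols if len(c) > 1]
    n_recovered = sum(1 for c in ref_cols if c in test_contents)
    cs_value = n_recovered / len(ref_cols) if ref_cols else 0.0
    return ScoreResult(
        sps=numerator / index.denominator_total,
        cs=cs_value,
        numerator=numerator,
        denominator=index.denominator_total,
        n_ref_columns_scored=len(index.column_contents),
    )


def cs(
    test: Alignment,
    ref: ReferenceAlignment,
    *,
    use_core_mask: bool = True,
    ignore_single_residue_columns: bool = False,
) -> float:
    """Column score only (see module docstring)."""
    return sps(
        test,
        ref,
        use_core_mask=use_core_mask,
        cs_ignore_single_residue_columns=ignore_single_residue_columns,
    ).cs


def score_case(
    test_path,
    ref_path,
    core_path=None,
    *,
    use_core_mask: bool = True,
    case_id: Optional[str] = None,
) -> ScoreResult:
    """File-level convenience wrapper: read, score, log one line."""
    bundle = load_case(ref_path, None, core_path, case_id=case_id)
    from .msa_io import read_alignment

    test = read_alignment(test_path)
    result = sps(test, bundle.reference, use_core_mask=use_core_mask)
    logger.info(
        "case %s: sps=%.4f cs=%.4f (%d/%d pairs)",
        bundle.case_id, result.sps, result.cs,
        result.numerator, result.denominator,
    )
    return result
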