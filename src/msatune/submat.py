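"""Substitution-score tables for the parameter sweep.

The sweep covers six classical protein matrices: BLOSUM30, BLOSUM45,
BLOSUM62, BLOSUM80, PAM100 and PAM200. The canonical NCBI integer tables are
loaded from biotite's matrix database at first use; user-supplied matrices in
the NCBI whitespace-table format are read with biopython.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Mapping

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Matrix names in the order the sweep iterates them (also the tie-break
#: order when two matrices achieve the same best score).
MATRIX_NAMES = ("BLOSUM30", "BLOSUM45", "BLOSUM62", "BLOSUM80", "PAM100", "PAM200")

_warned_residues: set[str] = set()


class SubstitutionMatrix:
    """A symmetric residue-pair score table over a fixed alphabet.

    Unknown residues are mapped to the ambiguity code ``X`` before lookup,
    so scoring never fails on rare codes (U, O, J ...) found in curated
    alignments.
    """

    def __init__(self, name: str, scores: Mapping[tuple[str, str], int]):
        self.name = name
        self.scores = {(a, b): int(v) for (a, b), v in scores.items()}
        self.alphabet = frozenset(a for a, _ in self.scores)
        for (a, b), v in self.scores.items():
            if self.scores.get((b, a)) != v:
                raise ConfigurationError(
                    f"matrix {name}: asymmetric entry {a}/{b}"
                )
        missing = [
            (a, b)
            for a in self.alphabet
            for b in self.alphabet
            if (a, b) not in self.scores
        ]
        if missing:
            raise ConfigurationError(
                f"matrix {name}: incomplete table, missing {missing[:3]}..."
            )
        if "X" not in self.alphabet:
            raise ConfigurationError(f"matrix {name}: no X ambiguity row")

    def _norm(self, a: str) -> str:
        a = a.upper()
        if a not in self.alphabet:
            if a not in _warned_residues:
                _warned_residues.add(a)
                logger.warning(
                    "residue %r not in matrix %s alphabet; scoring as X",
                    a, self.name,
                )
            return "X"
        return a

    def score(self, a: str, b: str) -> int:
        return self.scores[(self._norm(a), self._norm(b))]

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r}, |alphabet|={len(self.alphabet)})"


def get_matrix(name: str) -> SubstitutionMatrix:
    """Return one of the six packaged matrices by (case-insensitive) name."""
    canonical = name.upper()
    if canonical not in MATRIX_NAMES:
        raise ConfigurationError(
            f"unknown substitution matrix {name!r}; valid names: "
            + ", ".join(MATRIX_NAMES)
        )
    return _load_canonical(canonical)


@lru_cache(maxsize=None)
def _load_canonical(canonical: str) -> SubstitutionMatrix:
    from biotite.sequence.align import SubstitutionMatrix as _BtMatrix

    table = _BtMatrix.dict_from_db(canonical)
    return SubstitutionMatrix(canonical, table)


def load_matrix_file(path, name: str | None = None) -> SubstitutionMatrix:
    """Read a custom matrix in NCBI whitespace-table format from ``path``."""
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.read(str(path))
    letters = list(arr.alphabet)
    scores = {
        (a, b): int(arr[a, b]) for a in letters for b in letters
    }
    return SubstitutionMatrix(name or str(path), scores)


def pair_score(m: SubstitutionMatrix, a: str, b: str) -> int:
    """Score one residue pair; unknown residues are treated as ``X``."""
    return m.score(a, b)
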