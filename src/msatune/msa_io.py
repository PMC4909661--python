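"""Alignment and sequence containers plus readers/writers for the formats the
pipeline touches.

Formats: FASTA (aligned and unaligned), GCG MSF (read and write), and a
plain-text core-column annotation format (whitespace-separated 1-based
inclusive ranges, e.g. ``"3-10 25-40"``).

Conventions
-----------
* Gap characters ``-``, ``.`` and ``~`` are all accepted on input and
  normalised to ``-``; lowercase residues are upcased at parse time.
* Columns are 1-based inclusive in annotation files and reports, 0-based
  half-open everywhere internally.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence as TSequence

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import AlignmentFormatError

logger = logging.getLogger(__name__)

GAP_CHARS = "-.~"
_GAP_TRANS = str.maketrans({".": "-", "~": "-"})

#: Residues accepted by the parsers: the 20 standard amino acids plus the
#: ambiguity/rare codes seen in curated benchmark files.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO")


def _normalise(raw: str, *, what: str, ident: str) -> str:
    """Upcase, canonicalise gaps, and validate the residue alphabet."""
    s = raw.upper().translate(_GAP_TRANS)
    bad = set(s) - AMINO_ALPHABET - {"-"}
    if bad:
        raise AlignmentFormatError(
            f"{what} {ident!r} contains unsupported characters: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class Sequence:
    """An ungapped amino-acid sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentFormatError("sequence id must be nonempty")
        if not self.residues:
            raise AlignmentFormatError(f"sequence {self.id!r} is empty")
        if any(c in GAP_CHARS for c in self.residues):
            raise AlignmentFormatError(
                f"sequence {self.id!r} contains gap characters"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """A rectangular gapped sequence set.

    Rows keep their input order; every gapped string has the same length
    (``n_cols``) and ungaps to a valid :class:`Sequence`.
    """

    def __init__(self, rows: Iterable[tuple[str, str]]):
        rows = list(rows)
        if not rows:
            raise AlignmentFormatError("alignment has no rows")
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dup}")
        ncols = len(rows[0][1])
        for rid, gapped in rows:
            if len(gapped) != ncols:
                raise AlignmentFormatError(
                    f"ragged alignment: row {rid!r} has length "
                    f"{len(gapped)}, expected {ncols}"
                )
        self.rows: list[tuple[str, str]] = rows
        self.n_cols: int = ncols
        self.n_rows: int = len(rows)
        # validate ungapped content through the Sequence invariants
        for rid, gapped in rows:
            if not gapped.replace("-", ""):
                raise AlignmentFormatError(f"row {rid!r} is all gaps")
            Sequence(rid, gapped.replace("-", ""))

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def gapped(self, rid: str) -> str:
        for r, g in self.rows:
            if r == rid:
                return g
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.gapped(rid).replace("-", "")

    def sequences(self) -> list[Sequence]:
        return [Sequence(rid, g.replace("-", "")) for rid, g in self.rows]

    def columns(self) -> Iterator[list[str]]:
        """Yield columns as lists of characters, in row order."""
        for j in range(self.n_cols):
            yield [g[j] for _, g in self.rows]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.rows == other.rows

    def __repr__(self) -> str:
        return f"Alignment(n_rows={self.n_rows}, n_cols={self.n_cols})"


@dataclass
class ReferenceAlignment:
    """A reference (ground-truth) alignment, optionally with a core-column
    mask restricting which columns define scored residue pairs."""

    alignment: Alignment
    core_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.core_mask is not None:
            self.core_mask = np.asarray(self.core_mask, dtype=bool)
            if self.core_mask.shape != (self.alignment.n_cols,):
                raise AlignmentFormatError(
                    "core mask length "
                    f"{self.core_mask.size} != n_cols {self.alignment.n_cols}"
                )
            if not self.core_mask.any():
                raise AlignmentFormatError("core mask selects no columns")


@dataclass
class CaseBundle:
    """One benchmark case: a reference alignment plus its unaligned inputs."""

    case_id: str
    dataset_id: str
    reference: ReferenceAlignment
    inputs: list[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ref = self.reference.alignment
        in_ids = {s.id for s in self.inputs}
        if in_ids != set(ref.ids):
            raise AlignmentFormatError(
                f"case {self.case_id!r}: input ids {sorted(in_ids)} do not "
                f"match reference ids {sorted(ref.ids)}"
            )
        for s in self.inputs:
            if ref.ungapped(s.id) != s.residues:
                raise AlignmentFormatError(
                    f"case {self.case_id!r}: ungapped reference row "
                    f"{s.id!r} differs from the input sequence"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_fasta(path):
    try:
        return list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: FASTA parse failed: {exc}") from exc


def read_fasta_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = _parse_fasta(path)
    if not records:
        raise AlignmentFormatError(f"{path}: empty FASTA file")
    rows = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise AlignmentFormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        rows.append((rec.id, _normalise(str(rec.seq), what="record", ident=rec.id)))
    return Alignment(rows)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, gapped in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), 60):
                fh.write(gapped[i : i + 60] + "\n")


def read_sequences(path) -> list[Sequence]:
    """Read unaligned FASTA sequences; gaps, if present, are stripped."""
    records = _parse_fasta(path)
    if not records:
        raise AlignmentFormatError(f"{path}: empty FASTA file")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise AlignmentFormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        s = _normalise(str(rec.seq), what="record", ident=rec.id)
        if "-" in s:
            logger.warning("%s: stripping gap characters from %r", path, rec.id)
            s = s.replace("-", "")
        out.append(Sequence(rec.id, s))
    return out


def write_sequences(seqs: TSequence[Sequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GCG MSF
# ---------------------------------------------------------------------------

def read_msf_alignment(path) -> Alignment:
    """Read a GCG MSF alignment (the dialect curated protein benchmarks are
    distributed in); ``.`` and ``~`` gaps become ``-``."""
    text = Path(path).read_text()
    if ".." not in text:
        raise AlignmentFormatError(f"{path}: missing MSF '..' header separator")
    if "Check:" not in text:
        logger.warning("%s: MSF checksum section absent", path)
    try:
        msa = AlignIO.read(str(path), "msf")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: MSF parse failed: {exc}") from exc
    rows = [
        (rec.id, _normalise(str(rec.seq), what="record", ident=rec.id))
        for rec in msa
    ]
    return Alignment(rows)


def _gcg_checksum(seq: str) -> int:
    return sum(((i % 57) + 1) * ord(c) for i, c in enumerate(seq)) % 10000


def write_msf_alignment(aln: Alignment, path, name: str = "alignment") -> None:
    """Write a GCG MSF file (gaps as ``.``, 50-column interleaved blocks)."""
    today = datetime.date.today().strftime("%B %d, %Y")
    body = {rid: g.replace("-", ".") for rid, g in aln.rows}
    checks = {rid: _gcg_checksum(s) for rid, s in body.items()}
    total = sum(checks.values()) % 10000
    width = max(len(r) for r in body)
    with open(path, "w") as fh:
        fh.write("!!AA_MULTIPLE_ALIGNMENT 1.0\n\n")
        fh.write(
            f" {name}  MSF: {aln.n_cols}  Type: P  {today}  Check: {total} ..\n\n"
        )
        for rid in body:
            fh.write(
                f" Name: {rid:<{width}}  Len: {aln.n_cols}"
                f"  Check: {checks[rid]:>5}  Weight: 1.00\n"
            )
        fh.write("\n//\n\n")
        for start in range(0, aln.n_cols, 50):
            for rid, s in body.items():
                chunk = s[start : start + 50]
                pieces = " ".join(
                    chunk[i : i + 10] for i in range(0, len(chunk), 10)
                )
                fh.write(f"{rid:<{width}}  {pieces}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Core-column annotations
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def read_core_annotation(path, n_cols: int) -> np.ndarray:
    """Parse 1-based inclusive column ranges into a boolean mask of length
    ``n_cols``. Overlapping ranges are merged with a warning."""
    text = Path(path).read_text()
    mask = np.zeros(n_cols, dtype=bool)
    for tok in text.split():
        m = _RANGE_RE.match(tok)
        if not m:
            raise AlignmentFormatError(f"{path}: bad range token {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo < 1 or hi < lo:
            raise AlignmentFormatError(f"{path}: invalid range {tok!r}")
        if hi > n_cols:
            raise AlignmentFormatError(
                f"{path}: range {tok!r} exceeds alignment width {n_cols}"
            )
        if mask[lo - 1 : hi].any():
            logger.warning("%s: overlapping core range %r merged", path, tok)
        mask[lo - 1 : hi] = True
    if not mask.any():
        raise AlignmentFormatError(f"{path}: annotation selects no columns")
    return mask


# ---------------------------------------------------------------------------
# Benchmark-directory layout
# ---------------------------------------------------------------------------

def read_alignment(path) -> Alignment:
    """Dispatch on extension: ``.msf`` → MSF, anything else → FASTA."""
    if str(path).lower().endswith(".msf"):
        return read_msf_alignment(path)
    return read_fasta_alignment(path)


def load_case(ref_path, in_path=None, core_path=None, *, case_id=None,
              dataset_id="default") -> CaseBundle:
    """Load one case from explicit file paths.

    When ``in_path`` is omitted the inputs are the ungapped reference rows.
    """
    ref_aln = read_alignment(ref_path)
    mask = (
        read_core_annotation(core_path, ref_aln.n_cols) if core_path else None
    )
    inputs = read_sequences(in_path) if in_path else ref_aln.sequences()
    cid = case_id or Path(ref_path).stem.replace(".ref", "")
    return CaseBundle(cid, dataset_id, ReferenceAlignment(ref_aln, mask), inputs)


def load_benchmark_dir(root) -> list[CaseBundle]:
    """Load a benchmark tree laid out as ``root/<dataset>/<case>.ref.fasta``
    (or ``.ref.msf``) with ``<case>.in.fasta`` inputs and optional
    ``<case>.core`` annotations.

    Unreadable cases are skipped with an ERROR log; the rest load normally.
    """
    root = Path(root)
    cases: list[CaseBundle] = []
    for ds_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        refs = sorted(
            list(ds_dir.glob("*.ref.fasta")) + list(ds_dir.glob("*.ref.msf"))
        )
        for ref_path in refs:
            stem = ref_path.name.rsplit(".ref.", 1)[0]
            in_path = ds_dir / f"{stem}.in.fasta"
            core_path = ds_dir / f"{stem}.core"
            try:
                cases.append(
                    load_case(
                        ref_path,
                        in_path if in_path.exists() else None,
                        core_path if core_path.exists() else None,
                        case_id=stem,
                        dataset_id=ds_dir.name,
                    )
                )
            except AlignmentFormatError as exc:
                logger.error("skipping case %s: %s", stem, exc)
    return cases
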