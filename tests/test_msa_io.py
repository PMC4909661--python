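import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from msatune.errors import AlignmentFormatError
from msatune.msa_io import (
    Alignment,
    CaseBundle,
    ReferenceAlignment,
    Sequence,
    load_benchmark_dir,
    read_core_annotation,
    read_fasta_alignment,
    read_msf_alignment,
    read_sequences,
    write_fasta_alignment,
    write_msf_alignment,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nAC-D\n>s2\nACED\n")
        aln = read_fasta_alignment(p)
        assert (aln.n_rows, aln.n_cols) == (2, 4)
        assert aln.rows[0] == ("s1", "AC-D")

    def test_dot_gaps_and_case_normalised(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nac.d\n>s2\nACED\n")
        aln = read_fasta_alignment(p)
        assert aln.gapped("s1") == "AC-D"

    def test_ragged_records_name_offender(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nACDE\n>s2\nACDEF\n")
        with pytest.raises(AlignmentFormatError, match="s2"):
            read_fasta_alignment(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">s1\nACD\n>s1\nACD\n")
        with pytest.raises(AlignmentFormatError, match="duplicate"):
            read_fasta_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "a.fasta", "")
        with pytest.raises(AlignmentFormatError, match="empty"):
            read_fasta_alignment(p)

    def test_roundtrip(self, tmp_path, rng):
        from conftest import random_alignment_of

        seqs = {"s1": "ACDEFGHIKLMNPQRSTVWY" * 4, "s2": "WYACDEFGHIK" * 5}
        aln = random_alignment_of(seqs, rng)
        p = tmp_path / "rt.fasta"
        write_fasta_alignment(aln, p)
        assert read_fasta_alignment(p) == aln


class TestMsf:
    def test_roundtrip_interleaved_blocks(self, tmp_path, rng):
        # >50 columns forces multiple interleaved blocks
        from conftest import random_alignment_of

        seqs = {"alpha": "ACDEFGHIKL" * 7, "beta": "MNPQRSTVWY" * 6}
        aln = random_alignment_of(seqs, rng, extra_cols=20)
        p = tmp_path / "rt.msf"
        write_msf_alignment(aln, p)
        back = read_msf_alignment(p)
        assert back == aln

    def test_dot_gaps_normalised(self, tmp_path, rng):
        from conftest import random_alignment_of

        aln = random_alignment_of({"s1": "ACDE", "s2": "ACD"}, rng)
        p = tmp_path / "g.msf"
        write_msf_alignment(aln, p)  # writes '.' gaps per the MSF dialect
        assert "." in p.read_text()
        back = read_msf_alignment(p)
        for _, gapped in back.rows:
            assert set(gapped) <= set("ACDE-")

    def test_missing_separator_rejected(self, tmp_path):
        p = _write(tmp_path, "bad.msf", "!!AA_MULTIPLE_ALIGNMENT\nno separator\n")
        with pytest.raises(AlignmentFormatError, match=r"\.\."):
            read_msf_alignment(p)

    def test_declared_sequence_absent_from_blocks(self, tmp_path):
        text = (
            "!!AA_MULTIPLE_ALIGNMENT 1.0\n\n"
            " x.msf  MSF: 4  Type: P  today  Check: 0 ..\n\n"
            " Name: s1  Len: 4  Check: 0  Weight: 1.00\n"
            " Name: s2  Len: 4  Check: 0  Weight: 1.00\n"
            "\n//\n\n"
            "s1  ACDE\n\n"
        )
        p = _write(tmp_path, "bad.msf", text)
        with pytest.raises(AlignmentFormatError):
            read_msf_alignment(p)


class TestSequences:
    def test_gaps_stripped_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "s.fasta", ">a\nACD\n>b\nAC-D\n")
        with caplog.at_level(logging.WARNING):
            seqs = read_sequences(p)
        assert [s.residues for s in seqs] == ["ACD", "ACD"]
        assert any("stripping" in r.message for r in caplog.records)

    def test_empty_rejected(self, tmp_path):
        p = _write(tmp_path, "s.fasta", "\n")
        with pytest.raises(AlignmentFormatError):
            read_sequences(p)

    def test_order_preserved(self, tmp_path):
        p = _write(tmp_path, "s.fasta", ">c\nAA\n>a\nCC\n>b\nDD\n")
        assert [s.id for s in read_sequences(p)] == ["c", "a", "b"]

    def test_sequence_invariants(self):
        with pytest.raises(AlignmentFormatError):
            Sequence("x", "AC-D")
        with pytest.raises(AlignmentFormatError):
            Sequence("", "ACD")


class TestCoreAnnotation:
    @pytest.mark.parametrize(
        "text,n,expected",
        [
            ("1-2", 4, [True, True, False, False]),
            ("1-4", 4, [True, True, True, True]),
            ("3-10 25-40", 40, None),  # checked structurally below
        ],
    )
    def test_expansion(self, tmp_path, text, n, expected):
        p = _write(tmp_path, "c.core", text)
        mask = read_core_annotation(p, n)
        if expected is not None:
            assert mask.tolist() == expected
        else:
            assert mask[2:10].all() and mask[24:40].all()
            assert not mask[0] and not mask[10:24].any()

    def test_out_of_bounds(self, tmp_path):
        p = _write(tmp_path, "c.core", "2-9")
        with pytest.raises(AlignmentFormatError, match="exceeds"):
            read_core_annotation(p, 4)

    def test_overlap_merged_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "c.core", "1-3 2-4")
        with caplog.at_level(logging.WARNING):
            mask = read_core_annotation(p, 4)
        assert mask.all()
        assert any("overlap" in r.message for r in caplog.records)


class TestContainers:
    def test_core_mask_length_enforced(self):
        aln = Alignment([("a", "ACD"), ("b", "ACD")])
        with pytest.raises(AlignmentFormatError):
            ReferenceAlignment(aln, np.array([True, False]))

    def test_case_bundle_checks_content(self):
        aln = Alignment([("a", "AC-D"), ("b", "ACED")])
        ref = ReferenceAlignment(aln)
        with pytest.raises(AlignmentFormatError):
            CaseBundle("c", "d", ref, [Sequence("a", "ACD"), Sequence("b", "ACED" "X")])

    @given(st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        min_size=2, max_size=5, unique=True,
    ))
    def test_ungap_regap_roundtrip(self, residues):
        """Ungapping a row then re-inserting gaps at the recorded offsets
        reconstructs it exactly (gap bookkeeping is lossless)."""
        rng = np.random.default_rng(len("".join(residues)))
        from conftest import random_alignment_of

        seqs = {f"s{i}": r for i, r in enumerate(residues)}
        aln = random_alignment_of(seqs, rng)
        for rid, gapped in aln.rows:
            ungapped = gapped.replace("-", "")
            offsets = [j for j, c in enumerate(gapped) if c != "-"]
            rebuilt = ["-"] * aln.n_cols
            for off, c in zip(offsets, ungapped):
                rebuilt[off] = c
            assert "".join(rebuilt) == gapped
            assert ungapped == seqs[rid]


class TestBenchmarkLayout:
    def test_load_written_benchmark(self, tmp_path, caplog):
        from msatune.synthetic_data import PRESETS, generate_benchmark

        presets = {k: PRESETS[k] for k in ("RV12-like", "RV50-like")}
        manifest = generate_benchmark(2, presets, tmp_path / "bench")
        cases = load_benchmark_dir(tmp_path / "bench")
        assert len(cases) == len(manifest) == 4
        assert {c.dataset_id for c in cases} == set(presets)

        # a corrupt case is skipped with an ERROR log, others still load
        bad = tmp_path / "bench" / "RV12-like" / "broken.ref.fasta"
        bad.write_text(">s1\nACDE\n>s2\nACD\n")
        with caplog.at_level(logging.ERROR):
            cases2 = load_benchmark_dir(tmp_path / "bench")
        assert len(cases2) == 4
        assert any("skipping" in r.message for r in caplog.records)
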