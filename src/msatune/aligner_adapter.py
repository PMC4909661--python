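"""Run aligners — the builtin baseline or external command-line tools — on a
benchmark case with a given (matrix, GOP, GEP) combination.

External aligners are described by command templates with the placeholders
``{input}``, ``{output}``, ``{gop}``, ``{gep}`` and ``{matrix_flag}``; the
matrix flag fragment comes from a per-matrix map so tools with different
matrix vocabularies (e.g. MAFFT's ``--bl 62`` / ``--jtt 200``) can be
driven from one grid. Templates are split into argument vectors before
substitution — user data never passes through a shell.

Caveats worth knowing when sweeping MAFFT: its ``--ep`` offset is not a
textbook gap-extension penalty (values are passed verbatim), and it exposes
no Dayhoff-PAM flag, so the packaged map sends PAM100/PAM200 to the JTT-PAM
tables (``--jtt``); both mappings are overridable in the config file.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import yaml

from .errors import AlignerError, AlignmentIntegrityError, ConfigurationError
from .msa_io import Alignment, CaseBundle, read_fasta_alignment, write_sequences

if TYPE_CHECKING:  # pragma: no cover
    from .sweep import ParamCombo

logger = logging.getLogger(__name__)

_PLACEHOLDERS = ("{input}", "{output}")


@dataclass
class AlignerSpec:
    """How to invoke one aligner for any point of the parameter grid."""

    name: str
    command_template: str = ""
    matrix_flag_map: dict[str, str] = field(default_factory=dict)
    timeout_s: int = 600
    is_builtin: bool = False

    def __post_init__(self) -> None:
        if self.is_builtin:
            return
        for ph in _PLACEHOLDERS:
            if ph not in self.command_template:
                raise ConfigurationError(
                    f"aligner {self.name!r}: template lacks {ph}"
                )


def fmt_param(x: float) -> str:
    """Shortest decimal representation that round-trips the grid value."""
    return repr(float(x))


def render_command(spec: AlignerSpec, combo: "ParamCombo",
                   in_path, out_path) -> list[str]:
    """Substitute a grid point into the spec's template; returns argv."""
    if spec.is_builtin:
        raise ConfigurationError("builtin aligner has no command to render")
    if "{matrix_flag}" in spec.command_template:
        if combo.matrix not in spec.matrix_flag_map:
            raise ConfigurationError(
                f"aligner {spec.name!r}: no matrix flag mapped for "
                f"{combo.matrix!r}"
            )
        matrix_flag = spec.matrix_flag_map[combo.matrix]
    else:
        matrix_flag = ""
    subst = {
        "{input}": str(in_path),
        "{output}": str(out_path),
        "{gop}": fmt_param(combo.gop),
        "{gep}": fmt_param(combo.gep),
    }
    template = spec.command_template
    if _writes_stdout(spec):
        template = template[: template.rindex(">")]
    argv: list[str] = []
    for token in shlex.split(template):
        if token == "{matrix_flag}":
            argv.extend(shlex.split(matrix_flag))
            continue
        for ph, val in subst.items():
            token = token.replace(ph, val)
        argv.append(token)
    return argv


def _writes_stdout(spec: AlignerSpec) -> bool:
    """Templates ending in ``> {output}`` mean: capture stdout to the output
    file (tools like MAFFT write the alignment to stdout). No shell is used;
    the redirection is performed by the adapter itself."""
    return spec.command_template.rstrip().endswith("> {output}")


def run_aligner(spec: AlignerSpec, combo: "ParamCombo", case: CaseBundle,
                workdir) -> Alignment:
    """Align one case at one grid point.

    Raises :class:`AlignerError` on nonzero exit / timeout and
    :class:`AlignmentIntegrityError` when the output does not reproduce the
    input sequences; the sweep engine records these as FAILED cells.
    """
    if spec.is_builtin:
        from .baseline_aligner import progressive_align
        from .submat import get_matrix

        return progressive_align(
            case.inputs, get_matrix(combo.matrix), combo.gop, combo.gep
        )

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    in_path = workdir / f"{case.case_id}.in.fasta"
    out_path = workdir / f"{case.case_id}.out.fasta"
    try:
        write_sequences(case.inputs, in_path)
        argv = render_command(spec, combo, in_path, out_path)
        try:
            if _writes_stdout(spec):
                with open(out_path, "w") as out_fh:
                    proc = subprocess.run(
                        argv, stdout=out_fh, stderr=subprocess.PIPE,
                        text=True, timeout=spec.timeout_s,
                    )
            else:
                proc = subprocess.run(
                    argv, capture_output=True, text=True,
                    timeout=spec.timeout_s,
                )
        except subprocess.TimeoutExpired as exc:
            raise AlignerError(
                f"{spec.name} timed out after {spec.timeout_s}s on "
                f"{case.case_id}", stderr=str(exc)
            ) from exc
        except OSError as exc:
            raise AlignerError(
                f"{spec.name} could not be executed: {exc}", stderr=str(exc)
            ) from exc
        if proc.returncode != 0:
            raise AlignerError(
                f"{spec.name} exited {proc.returncode} on {case.case_id}",
                stderr=proc.stderr,
            )
        if not out_path.exists():
            raise AlignerError(
                f"{spec.name} produced no output for {case.case_id}",
                stderr=proc.stderr,
            )
        aln = read_fasta_alignment(out_path)
        _verify_integrity(aln, case)
        return aln
    finally:
        for p in (in_path, out_path):
            p.unlink(missing_ok=True)


def _verify_integrity(aln: Alignment, case: CaseBundle) -> None:
    want = {s.id: s.residues for s in case.inputs}
    got = {rid: aln.ungapped(rid) for rid in aln.ids}
    if set(got) != set(want):
        raise AlignmentIntegrityError(
            f"{case.case_id}: output ids {sorted(got)} != input ids "
            f"{sorted(want)}"
        )
    for rid, res in want.items():
        if got[rid].upper() != res.upper():
            raise AlignmentIntegrityError(
                f"{case.case_id}: output row {rid!r} does not ungap to its input"
            )


# ---------------------------------------------------------------------------
# Packaged specs & config files
# ---------------------------------------------------------------------------

_MAFFT_BL_MAP = {
    "BLOSUM30": "--bl 30",
    "BLOSUM45": "--bl 45",
    "BLOSUM62": "--bl 62",
    "BLOSUM80": "--bl 80",
    # MAFFT has no Dayhoff-PAM option; JTT-PAM is the closest flag. Override
    # with --aamatrix <file> in a custom config for true Dayhoff tables.
    "PAM100": "--jtt 100",
    "PAM200": "--jtt 200",
}


def builtin_spec() -> AlignerSpec:
    return AlignerSpec(name="builtin", is_builtin=True)


def packaged_specs() -> dict[str, AlignerSpec]:
    """Example external-aligner templates (editable via a YAML config)."""
    return {
        "builtin": builtin_spec(),
        "mafft-linsi": AlignerSpec(
            name="mafft-linsi",
            command_template=(
                "mafft --localpair --maxiterate 1000 --quiet "
                "--op {gop} --ep {gep} {matrix_flag} {input} > {output}"
            ),
            matrix_flag_map=dict(_MAFFT_BL_MAP),
        ),
        "clustalw": AlignerSpec(
            name="clustalw",
            command_template=(
                "clustalw2 -INFILE={input} -OUTFILE={output} -OUTPUT=FASTA "
                "-GAPOPEN={gop} -GAPEXT={gep} {matrix_flag}"
            ),
            matrix_flag_map={
                "BLOSUM30": "-MATRIX=BLOSUM",
                "BLOSUM45": "-MATRIX=BLOSUM",
                "BLOSUM62": "-MATRIX=BLOSUM",
                "BLOSUM80": "-MATRIX=BLOSUM",
                "PAM100": "-MATRIX=PAM",
                "PAM200": "-MATRIX=PAM",
            },
        ),
    }


def load_aligner_config(path) -> dict[str, AlignerSpec]:
    """Load AlignerSpecs from a YAML file: ``{name: {command_template: ...,
    matrix_flag_map: {...}, timeout_s: ...}}``. The builtin aligner is
    always available under the name ``builtin``."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    specs = {"builtin": builtin_spec()}
    for name, cfg in data.items():
        specs[name] = AlignerSpec(
            name=name,
            command_template=cfg.get("command_template", ""),
            matrix_flag_map=dict(cfg.get("matrix_flag_map", {})),
            timeout_s=int(cfg.get("timeout_s", 600)),
            is_builtin=bool(cfg.get("is_builtin", False)),
        )
    return specs


def get_aligner(name: str, config_path=None) -> AlignerSpec:
    specs = load_aligner_config(config_path) if config_path else packaged_specs()
    if name not in specs:
        raise ConfigurationError(
            f"unknown aligner {name!r}; available: {sorted(specs)}"
        )
    return specs[name]
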