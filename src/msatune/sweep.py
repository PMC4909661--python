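"""Parameter-grid generation and the (cases × combinations) sweep engine.

The grid is the Cartesian product of a substitution-matrix list with evenly
stepped GOP and GEP values (default steps 0.1 and 0.03). Grid values are
generated as integer multiples of the step in decimal arithmetic and
rounded to the step's precision, so 1.2 is 1.2 — never
1.2000000000000002 — and combinations serialise losslessly and act as
stable checkpoint keys.

The sweep writes one TSV record per (case, combination) as it goes and can
resume from that checkpoint without re-running finished cells. Failed
aligner runs are recorded with status FAILED, never dropped silently.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence as TSequence

import pandas as pd

from .aligner_adapter import AlignerSpec, run_aligner
from .errors import AlignerError, ConfigurationError
from .msa_io import CaseBundle
from .scoring import sps
from .submat import MATRIX_NAMES

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "dataset_id", "case_id", "matrix", "gop", "gep",
    "sps", "cs", "status", "runtime_s",
]


@dataclass(frozen=True, order=True)
class ParamCombo:
    """One grid point: substitution matrix + gap open/extension penalties."""

    matrix: str
    gop: float
    gep: float

    def key(self) -> tuple[str, str, str]:
        return (self.matrix, repr(self.gop), repr(self.gep))


@dataclass
class GridSpec:
    """Ranges and steps of the GOP × GEP × matrix grid."""

    gop_min: float = 0.1
    gop_max: float = 3.0
    gop_step: float = 0.1
    gep_min: float = 0.03
    gep_max: float = 1.50
    gep_step: float = 0.03
    matrices: TSequence[str] = field(default_factory=lambda: list(MATRIX_NAMES))


def _decimal_range(mn: float, mx: float, step: float) -> list[float]:
    dmn, dmx, dst = Decimal(str(mn)), Decimal(str(mx)), Decimal(str(step))
    if dst <= 0:
        raise ConfigurationError("grid step must be positive")
    if dmn > dmx:
        raise ConfigurationError("grid min exceeds max")
    out = []
    k = 0
    while True:
        v = dmn + k * dst
        if v > dmx:
            break
        out.append(float(v))
        k += 1
    return out


def build_grid(spec: GridSpec) -> list[ParamCombo]:
    """Enumerate the grid in deterministic order: matrix list order, then
    GOP ascending, then GEP ascending."""
    if not spec.matrices:
        raise ConfigurationError("grid has no matrices")
    gops = _decimal_range(spec.gop_min, spec.gop_max, spec.gop_step)
    geps = _decimal_range(spec.gep_min, spec.gep_max, spec.gep_step)
    if not gops or not geps:
        raise ConfigurationError("empty grid")
    return [
        ParamCombo(m, gop, gep)
        for m in spec.matrices
        for gop in gops
        for gep in geps
    ]


def _load_checkpoint(path: Path) -> tuple[list[dict], set]:
    if not path.exists() or path.stat().st_size == 0:
        return [], set()
    df = pd.read_csv(path, sep="\t", dtype={"matrix": str},
                     float_precision="round_trip")
    records = df.to_dict("records")
    done = {
        (r["case_id"], r["matrix"], repr(float(r["gop"])), repr(float(r["gep"])))
        for r in records
    }
    return records, done


def run_sweep(
    cases: TSequence[CaseBundle],
    grid: TSequence[ParamCombo],
    spec: AlignerSpec,
    out_path,
    *,
    workdir=None,
    use_core_mask: bool = True,
    resume: bool = True,
) -> pd.DataFrame:
    """Score every (case, combination) cell; returns the sorted SweepTable.

    The table is checkpointed to ``out_path`` record-by-record; with
    ``resume=True`` an existing checkpoint is honoured and finished cells
    are not recomputed.
    """
    if not cases or not grid:
        raise ConfigurationError("sweep needs at least one case and one combo")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    workdir = Path(workdir) if workdir else out_path.parent / "work"

    records, done = _load_checkpoint(out_path) if resume else ([], set())
    mode = "a" if (resume and out_path.exists() and records) else "w"
    with open(out_path, mode, newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SWEEP_COLUMNS, delimiter="\t")
        if mode == "w":
            writer.writeheader()
        total = len(cases) * len(grid)
        n_done = len(records)
        for case in cases:
            for combo in grid:
                if (case.case_id, *combo.key()) in done:
                    continue
                t0 = time.perf_counter()
                try:
                    aln = run_aligner(spec, combo, case, workdir)
                    result = sps(aln, case.reference, use_core_mask=use_core_mask)
                    rec = {
                        "dataset_id": case.dataset_id,
                        "case_id": case.case_id,
                        "matrix": combo.matrix,
                        "gop": combo.gop,
                        "gep": combo.gep,
                        "sps": result.sps,
                        "cs": result.cs,
                        "status": "OK",
                        "runtime_s": round(time.perf_counter() - t0, 4),
                    }
                except AlignerError as exc:
                    logger.warning(
                        "FAILED %s @ %s: %s", case.case_id, combo, exc
                    )
                    rec = {
                        "dataset_id": case.dataset_id,
                        "case_id": case.case_id,
                        "matrix": combo.matrix,
                        "gop": combo.gop,
                        "gep": combo.gep,
                        "sps": "",
                        "cs": "",
                        "status": "FAILED",
                        "runtime_s": round(time.perf_counter() - t0, 4),
                    }
                writer.writerow(rec)
                fh.flush()
                records.append(rec)
                n_done += 1
                if n_done % 50 == 0 or n_done == total:
                    logger.info("sweep progress: %d/%d cells", n_done, total)

    df = pd.DataFrame(records, columns=SWEEP_COLUMNS)
    df["sps"] = pd.to_numeric(df["sps"], errors="coerce")
    df["cs"] = pd.to_numeric(df["cs"], errors="coerce")
    df = df.sort_values(
        ["dataset_id", "case_id", "matrix", "gop", "gep"]
    ).reset_index(drop=True)
    # shortest round-tripping decimal repr so the TSV reloads losslessly
    df.to_csv(out_path, sep="\t", index=False,
              float_format=lambda v: repr(float(v)))
    return df


def read_sweep_table(path) -> pd.DataFrame:
    """Load a sweep TSV produced by :func:`run_sweep`."""
    df = pd.read_csv(path, sep="\t", dtype={"matrix": str},
                     float_precision="round_trip")
    missing = set(SWEEP_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing sweep columns {sorted(missing)}")
    return df
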