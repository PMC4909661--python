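"""Reductions of a sweep table to parameter recommendations.

The selection procedure mirrors standard benchmark practice:

1. every (case, matrix, GOP, GEP) cell holds one SPS value;
2. **MEAN_SPS** — the unweighted mean SPS over a dataset's cases at one
   (matrix, GOP, GEP) combination;
3. **MAX_MEAN_SPS** — for each matrix, the maximum MEAN_SPS over the
   GOP × GEP grid, together with its argmax penalties;
4. the **optimal matrix** for a dataset is the one whose MAX_MEAN_SPS is
   largest; its argmax (GOP, GEP) are the optimal penalties.

Ties are broken deterministically: smallest GOP, then smallest GEP, then
matrix list order. Means are printed at 4 decimals in reports but compared
at full precision so rounding can never flip a ranking.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence as TSequence

import pandas as pd

from .aligner_adapter import AlignerSpec, run_aligner
from .errors import AlignerError, ConfigurationError
from .msa_io import CaseBundle
from .scoring import sps as _sps_score
from .submat import MATRIX_NAMES
from .sweep import ParamCombo

logger = logging.getLogger(__name__)

#: MAFFT's stock progressive/iterative parameter set, used as the packaged
#: "default" entry in comparison reports.
MAFFT_DEFAULT_COMBO = ParamCombo("BLOSUM62", 1.53, 0.123)


def mean_sps(table: pd.DataFrame) -> pd.DataFrame:
    """MEAN_SPS per (dataset, matrix, gop, gep); FAILED cells are excluded
    from the mean and counted in ``n_failed``."""
    if table.empty:
        raise ConfigurationError("empty sweep table")
    grouped = table.groupby(["dataset_id", "matrix", "gop", "gep"], sort=True)
    rows = []
    for key, grp in grouped:
        ok = grp[grp["status"] == "OK"]
        n_failed = int((grp["status"] == "FAILED").sum())
        if ok.empty:
            logger.warning(
                "group %s has no successful cells; MEAN_SPS undefined", key
            )
            mean = float("nan")
        else:
            mean = float(ok["sps"].mean())
        rows.append(
            {
                "dataset_id": key[0],
                "matrix": key[1],
                "gop": float(key[2]),
                "gep": float(key[3]),
                "mean_sps": mean,
                "n_cases": int(len(grp)),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)


def max_mean_sps(means: pd.DataFrame) -> pd.DataFrame:
    """MAX_MEAN_SPS per (dataset, matrix) with its argmax (gop, gep).

    Ties take the smallest gop, then the smallest gep.
    """
    if means.empty:
        raise ConfigurationError("empty MEAN_SPS table")
    df = means.dropna(subset=["mean_sps"]).sort_values(
        ["dataset_id", "matrix", "gop", "gep"], kind="mergesort"
    )
    idx = df.groupby(["dataset_id", "matrix"], sort=True)["mean_sps"].idxmax()
    out = df.loc[idx, ["dataset_id", "matrix", "mean_sps", "gop", "gep"]]
    out = out.rename(
        columns={"mean_sps": "max_mean_sps", "gop": "argmax_gop", "gep": "argmax_gep"}
    )
    return out.reset_index(drop=True)


def select_optimal(
    rows: pd.DataFrame,
    matrix_order: TSequence[str] = MATRIX_NAMES,
) -> pd.DataFrame:
    """Per dataset, the matrix (and penalties) with the largest
    MAX_MEAN_SPS; ties broken by ``matrix_order``."""
    if rows.empty:
        raise ConfigurationError("empty MAX_MEAN_SPS table")
    order = {m: i for i, m in enumerate(matrix_order)}
    df = rows.copy()
    df["_rank"] = df["matrix"].map(lambda m: order.get(m, len(order)))
    df = df.sort_values(["dataset_id", "_rank"], kind="mergesort")
    idx = df.groupby("dataset_id", sort=True)["max_mean_sps"].idxmax()
    out = df.loc[idx].drop(columns="_rank")
    out = out.rename(
        columns={
            "max_mean_sps": "best_max_mean_sps",
            "argmax_gop": "gop",
            "argmax_gep": "gep",
        }
    )
    cols = ["dataset_id", "matrix", "best_max_mean_sps"]
    if "gop" in out.columns:
        cols += ["gop", "gep"]
    return out[cols].reset_index(drop=True)


def optimize(table: pd.DataFrame) -> pd.DataFrame:
    """One-call reduction: sweep table → optimal parameters per dataset."""
    return select_optimal(max_mean_sps(mean_sps(table)))


# ---------------------------------------------------------------------------
# Named-set comparisons (default-vs-optimised reports)
# ---------------------------------------------------------------------------

def compare_parameter_sets(
    cases: TSequence[CaseBundle],
    named_sets: Mapping[str, ParamCombo | Mapping[str, ParamCombo]],
    spec: AlignerSpec,
    *,
    workdir=None,
    use_core_mask: bool = True,
) -> pd.DataFrame:
    """Re-run each named parameter set over ``cases`` and report the mean
    SPS per dataset (rows = set names, columns = datasets).

    A named set is either one :class:`ParamCombo` applied to every dataset
    or a per-dataset mapping (as produced by :func:`optimal_combos`).
    The result carries ``df.attrs['mode'] = 'rerun'``.
    """
    if not named_sets:
        raise ConfigurationError("no parameter sets to compare")
    import tempfile

    datasets = sorted({c.dataset_id for c in cases})
    rows = {}
    with tempfile.TemporaryDirectory() as tmp:
        wd = workdir or tmp
        for name, combos in named_sets.items():
            per_ds = {}
            for ds in datasets:
                ds_cases = [c for c in cases if c.dataset_id == ds]
                combo = combos[ds] if isinstance(combos, Mapping) else combos
                vals = []
                for case in ds_cases:
                    try:
                        aln = run_aligner(spec, combo, case, wd)
                        vals.append(
                            _sps_score(
                                aln, case.reference, use_core_mask=use_core_mask
                            ).sps
                        )
                    except AlignerError as exc:
                        logger.warning(
                            "comparison %s: case %s FAILED: %s",
                            name, case.case_id, exc,
                        )
                per_ds[ds] = sum(vals) / len(vals) if vals else float("nan")
            rows[name] = per_ds
    df = pd.DataFrame(rows).T[datasets]
    df.index.name = "parameter_set"
    df.attrs["mode"] = "rerun"
    return df


def compare_from_sweep(
    table: pd.DataFrame,
    named_sets: Mapping[str, ParamCombo | Mapping[str, ParamCombo]],
) -> pd.DataFrame:
    """Quote-mode comparison: look each named set's cells up in an existing
    sweep table instead of re-running the aligner. Carries
    ``df.attrs['mode'] = 'quote'``."""
    if not named_sets:
        raise ConfigurationError("no parameter sets to compare")
    means = mean_sps(table)
    datasets = sorted(means["dataset_id"].unique())
    rows = {}
    for name, combos in named_sets.items():
        per_ds = {}
        for ds in datasets:
            combo = combos[ds] if isinstance(combos, Mapping) else combos
            sel = means[
                (means["dataset_id"] == ds)
                & (means["matrix"] == combo.matrix)
                & (means["gop"] == combo.gop)
                & (means["gep"] == combo.gep)
            ]
            if sel.empty:
                raise ConfigurationError(
                    f"set {name!r}: combo {combo} absent from sweep table "
                    f"for dataset {ds}"
                )
            per_ds[ds] = float(sel["mean_sps"].iloc[0])
        rows[name] = per_ds
    df = pd.DataFrame(rows).T[datasets]
    df.index.name = "parameter_set"
    df.attrs["mode"] = "quote"
    return df


def optimal_combos(optimal: pd.DataFrame) -> dict[str, ParamCombo]:
    """Turn a :func:`select_optimal` result into a per-dataset combo map."""
    return {
        r["dataset_id"]: ParamCombo(r["matrix"], float(r["gop"]), float(r["gep"]))
        for _, r in optimal.iterrows()
    }
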