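import numpy as np
import pandas as pd
import pytest

from msatune.aggregate import (
    MAFFT_DEFAULT_COMBO,
    compare_from_sweep,
    compare_parameter_sets,
    max_mean_sps,
    mean_sps,
    optimal_combos,
    optimize,
    select_optimal,
)
from msatune.aligner_adapter import builtin_spec
from msatune.submat import MATRIX_NAMES
from msatune.sweep import GridSpec, ParamCombo, build_grid, run_sweep
from msatune.synthetic_data import PRESETS, generate_cases
from oracles import bruteforce_optimum


def _table(records):
    rows = []
    for ds, case, m, gop, gep, sps in records:
        rows.append(
            dict(dataset_id=ds, case_id=case, matrix=m, gop=gop, gep=gep,
                 sps=sps, cs=np.nan,
                 status="OK" if sps == sps else "FAILED", runtime_s=0.0)
        )
    return pd.DataFrame(rows)


class TestMeanSps:
    def test_arithmetic_mean(self):
        t = _table([
            ("D", "c1", "BLOSUM62", 1.0, 0.03, 0.5),
            ("D", "c2", "BLOSUM62", 1.0, 0.03, 0.7),
        ])
        out = mean_sps(t)
        assert out.loc[0, "mean_sps"] == pytest.approx(0.6)
        assert out.loc[0, "n_cases"] == 2

    def test_single_case_identity(self):
        t = _table([("D", "c1", "BLOSUM62", 1.0, 0.03, 0.42)])
        assert mean_sps(t).loc[0, "mean_sps"] == pytest.approx(0.42)

    def test_failed_cells_excluded_and_counted(self):
        t = _table([
            ("D", "c1", "BLOSUM62", 1.0, 0.03, 0.4),
            ("D", "c2", "BLOSUM62", 1.0, 0.03, float("nan")),
            ("D", "c3", "BLOSUM62", 1.0, 0.03, 0.8),
        ])
        out = mean_sps(t)
        assert out.loc[0, "mean_sps"] == pytest.approx(0.6)
        assert out.loc[0, "n_failed"] == 1

    def test_all_failed_group_is_nan_with_warning(self, caplog):
        t = _table([("D", "c1", "BLOSUM62", 1.0, 0.03, float("nan"))])
        import logging

        with caplog.at_level(logging.WARNING):
            out = mean_sps(t)
        assert np.isnan(out.loc[0, "mean_sps"])
        assert any("no successful" in r.message for r in caplog.records)


class TestMaxMeanSps:
    def test_picks_maximum(self):
        t = _table([
            ("D", "c1", "BLOSUM62", 1.0, 0.03, 0.5),
            ("D", "c1", "BLOSUM62", 2.0, 0.03, 0.9),
        ])
        row = max_mean_sps(mean_sps(t)).iloc[0]
        assert row["max_mean_sps"] == pytest.approx(0.9)
        assert (row["argmax_gop"], row["argmax_gep"]) == (2.0, 0.03)

    def test_tie_takes_smallest_gop(self):
        t = _table([
            ("D", "c1", "BLOSUM62", 2.0, 0.03, 0.9),
            ("D", "c1", "BLOSUM62", 1.0, 0.03, 0.9),
        ])
        row = max_mean_sps(mean_sps(t)).iloc[0]
        assert row["argmax_gop"] == 1.0


class TestSelectOptimal:
    # per-matrix best mean scores measured for two benchmark datasets with
    # known winners: a family+orphan set (BLOSUM62 wins) and a
    # low-identity set (BLOSUM45 wins)
    RV20 = [0.8532, 0.8577, 0.8594, 0.8573, 0.8535, 0.8518]
    RV11 = [0.5201, 0.5912, 0.5791, 0.5770, 0.5453, 0.5415]

    @staticmethod
    def _rows(ds, values):
        return pd.DataFrame(
            [
                {"dataset_id": ds, "matrix": m, "max_mean_sps": v,
                 "argmax_gop": 1.0, "argmax_gep": 0.03}
                for m, v in zip(MATRIX_NAMES, values)
            ]
        )

    def test_family_orphan_set_selects_blosum62(self):
        out = select_optimal(self._rows("RV20", self.RV20))
        assert out.loc[0, "matrix"] == "BLOSUM62"
        assert out.loc[0, "best_max_mean_sps"] == pytest.approx(0.8594)

    def test_low_identity_set_selects_blosum45(self):
        out = select_optimal(self._rows("RV11", self.RV11))
        assert out.loc[0, "matrix"] == "BLOSUM45"
        assert out.loc[0, "best_max_mean_sps"] == pytest.approx(0.5912)

    def test_single_matrix_passthrough(self):
        rows = self._rows("D", [0.5]).iloc[:1]
        assert select_optimal(rows).loc[0, "matrix"] == "BLOSUM30"

    def test_tie_broken_by_matrix_order(self):
        rows = self._rows("D", [0.5, 0.7, 0.7, 0.1, 0.1, 0.1])
        assert select_optimal(rows).loc[0, "matrix"] == "BLOSUM45"


class TestReductionOracle:
    def _random_table(self, rng):
        n_ds = rng.integers(1, 3)
        records = []
        for d in range(n_ds):
            ds = f"DS{d}"
            cases = [f"c{i}" for i in range(rng.integers(1, 6))]
            n_m = rng.integers(1, 4)
            mats = list(rng.choice(MATRIX_NAMES, size=n_m, replace=False))
            gops = [round(float(g), 1) for g in rng.choice([0.5, 1.0, 1.5, 2.0], size=rng.integers(1, 4), replace=False)]
            geps = [round(float(g), 2) for g in rng.choice([0.03, 0.3, 0.9], size=rng.integers(1, 3), replace=False)]
            for c in cases:
                for m in mats:
                    for gop in gops:
                        for gep in geps:
                            sps_val = (
                                float("nan")
                                if rng.random() < 0.05
                                else round(float(rng.random()), 3)
                            )
                            records.append((ds, c, m, gop, gep, sps_val))
        return _table(records)

    def test_chain_equals_bruteforce_scan(self, rng):
        """select_optimal ∘ max_mean_sps ∘ mean_sps equals a one-pass
        argmax over the raw records, on random sweep tables."""
        for _ in range(50):
            t = self._random_table(rng)
            if not (t["status"] == "OK").any():
                continue
            got = optimize(t)
            want = bruteforce_optimum(t.to_dict("records"), MATRIX_NAMES)
            assert len(got) == len(want)
            for _, row in got.iterrows():
                w = want[row["dataset_id"]]
                assert row["matrix"] == w["matrix"]
                assert row["best_max_mean_sps"] == pytest.approx(w["mean_sps"])
                assert (row["gop"], row["gep"]) == (w["gop"], w["gep"])

    def test_permutation_invariance(self, rng):
        t = self._random_table(rng)
        shuffled = t.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = optimize(t).reset_index(drop=True)
        b = optimize(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def small_sweep(tmp_path_factory):
    cases = generate_cases(
        {"D1": PRESETS["RV12-like"], "D2": PRESETS["RV50-like"]}, 2
    )
    grid = build_grid(GridSpec(
        gop_min=0.53, gop_max=2.53, gop_step=1.0,
        gep_min=0.123, gep_max=0.923, gep_step=0.4,
        matrices=["BLOSUM62", "BLOSUM45"],
    ))
    assert ParamCombo("BLOSUM62", 1.53, 0.123) in grid
    out = tmp_path_factory.mktemp("sweep") / "s.tsv"
    return cases, grid, run_sweep(cases, grid, builtin_spec(), out)


class TestComparisons:
    def test_max_dominates_every_combo_mean(self, small_sweep):
        _, _, table = small_sweep
        means = mean_sps(table)
        best = select_optimal(max_mean_sps(means))
        for _, row in best.iterrows():
            ds_means = means[means["dataset_id"] == row["dataset_id"]]
            assert row["best_max_mean_sps"] >= ds_means["mean_sps"].max() - 1e-12

    def test_quote_mode_self_consistency(self, small_sweep):
        _, _, table = small_sweep
        best = optimize(table)
        named = {
            "measured": optimal_combos(best),
            "mafft-default": MAFFT_DEFAULT_COMBO,
        }
        cmp_df = compare_from_sweep(table, named)
        assert cmp_df.attrs["mode"] == "quote"
        for _, row in best.iterrows():
            ds = row["dataset_id"]
            assert cmp_df.loc["measured", ds] == pytest.approx(
                row["best_max_mean_sps"]
            )
            # optimum over a grid containing the default cannot lose to it
            assert (
                cmp_df.loc["measured", ds]
                >= cmp_df.loc["mafft-default", ds] - 1e-12
            )

    def test_identical_named_sets_identical_rows(self, small_sweep):
        _, _, table = small_sweep
        combo = MAFFT_DEFAULT_COMBO
        cmp_df = compare_from_sweep(table, {"a": combo, "b": combo})
        assert cmp_df.loc["a"].equals(cmp_df.loc["b"])

    def test_rerun_mode_matches_quote_mode_for_builtin(self, small_sweep):
        cases, _, table = small_sweep
        named = {"default": MAFFT_DEFAULT_COMBO}
        rerun = compare_parameter_sets(cases, named, builtin_spec())
        quoted = compare_from_sweep(table, named)
        assert rerun.attrs["mode"] == "rerun"
        for ds in quoted.columns:
            assert rerun.loc["default", ds] == pytest.approx(
                quoted.loc["default", ds]
            )
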