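"""Threshold calibration, flagging, ranking and the screen transformer."""

import numpy as np
import pandas as pd
import pytest

from cns_screen.screening import (
    DEFAULT_THRESHOLDS, STRICT_THRESHOLDS, CompoundScreen, ThresholdSet,
    calibrate_thresholds, rank, screen,
)


def toy_candidates():
    return pd.DataFrame({
        "cns_mpo": [4.5, 3.2, 2.0],
        "bbb_score": [4.8, 4.1, 3.0],
        "neg_logs": [5.0, 7.5, 9.0],
        "mpa": [55.0, 60.0, 70.0],
    }, index=pd.Index(["A", "B", "C"], name="compound_id"))


class TestCalibrateThresholds:
    def test_guideline_values_reproduce_printed_criteria(self):
        panel = pd.DataFrame({"herg": [4.1, 5.0], "cns_mpo": [3.5, 4.2]})
        ts, audit = calibrate_thresholds(panel)
        assert ts.herg_max == 5.5
        assert ts.neg_logs_max == 7.5
        assert ts.bbb_score_min == 4.0
        assert ts.mpa_max == 60.0
        assert ts.cns_mpo_min == 3.0
        assert ts.clogd_max is None

    def test_strict_preset_raises_mpo_cutoff_to_four(self):
        panel = pd.DataFrame({"herg": [4.1]})
        ts, _ = calibrate_thresholds(panel, preset="strict")
        assert ts.cns_mpo_min == 4.0

    def test_audit_reports_panel_ranges(self):
        panel = pd.DataFrame({"herg": [4.1, 5.0], "cns_mpo": [3.5, 4.2]})
        _, audit = calibrate_thresholds(panel)
        assert audit.loc["herg", "min"] == 4.1
        assert audit.loc["herg", "max"] == 5.0

    def test_single_compound_panel_min_equals_max(self):
        panel = pd.DataFrame({"herg": [4.7], "cns_mpo": [3.9]})
        _, audit = calibrate_thresholds(panel)
        assert (audit["min"] == audit["max"]).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(pd.DataFrame())


class TestScreen:
    def test_herg_above_cutoff_fails(self):
        cands = toy_candidates()
        ext = pd.DataFrame({"herg": [6.0, 5.0, 5.5]}, index=cands.index)
        out = screen(cands, DEFAULT_THRESHOLDS, ext)
        assert out.loc["A", "pass_herg"] is False
        assert out.loc["B", "pass_herg"] is True
        assert out.loc["C", "pass_herg"] is True  # inclusive boundary

    def test_boundary_candidate_passes_everything(self):
        cands = pd.DataFrame({
            "cns_mpo": [3.0], "bbb_score": [4.0], "neg_logs": [7.5],
            "mpa": [60.0],
        }, index=pd.Index(["EDGE"], name="compound_id"))
        ext = pd.DataFrame({"herg": [5.5]}, index=cands.index)
        out = screen(cands, DEFAULT_THRESHOLDS, ext)
        flags = [c for c in out.columns if c.startswith("pass_")]
        assert all(out.loc["EDGE", f] is True for f in flags)
        assert out.loc["EDGE", "n_pass"] == 5

    def test_missing_external_column_is_not_evaluated(self):
        out = screen(toy_candidates(), DEFAULT_THRESHOLDS, external=None)
        assert out["pass_herg"].isna().all()
        # n_pass counts only evaluated passes
        assert out.loc["A", "n_pass"] == 4

    def test_flags_depend_only_on_own_row(self):
        cands = toy_candidates()
        out_all = screen(cands, DEFAULT_THRESHOLDS)
        out_one = screen(cands.loc[["B"]], DEFAULT_THRESHOLDS)
        pd.testing.assert_series_equal(out_all.loc["B"], out_one.loc["B"])

    def test_empty_input_gives_empty_result(self):
        out = screen(toy_candidates().iloc[:0], DEFAULT_THRESHOLDS)
        assert len(out) == 0

    def test_frozen_hr_fixture_matches_independent_flag_loop(self, hr_screen_oracle):
        score_cols = ["cns_mpo", "bbb_score", "neg_logs", "mpa", "clogd_74"]
        cands = hr_screen_oracle[score_cols]
        ext = hr_screen_oracle[["herg"]]
        out = screen(cands, DEFAULT_THRESHOLDS, ext)
        cuts = {"herg": (5.5, "le"), "neg_logs": (7.5, "le"),
                "cns_mpo": (3.0, "ge"), "bbb_score": (4.0, "ge"),
                "mpa": (60.0, "le")}
        joined = hr_screen_oracle.join(out[[c for c in out.columns
                                            if c.startswith("pass_") or c == "n_pass"]])
        for cid, row in joined.iterrows():
            n_pass_loop = 0
            for col, (cut, direction) in cuts.items():
                v = row[col]
                got = row[f"pass_{col}"]
                if pd.isna(v):
                    assert pd.isna(got)
                    continue
                want = (v <= cut) if direction == "le" else (v >= cut)
                assert got == want, (cid, col)
                n_pass_loop += int(want)
            assert row["n_pass"] == n_pass_loop == row["exp_n_pass"]


class TestRank:
    def test_higher_mpo_ranks_first_on_tie(self):
        df = pd.DataFrame({
            "n_pass": [4, 4], "cns_mpo": [3.5, 4.0],
            "bbb_score": [4.0, 4.0], "neg_logs": [5.0, 5.0],
        }, index=pd.Index(["X", "Y"], name="compound_id"))
        out = rank(df)
        assert list(out.index) == ["Y", "X"]

    def test_identical_rows_break_ties_alphabetically(self):
        df = pd.DataFrame({
            "n_pass": [3, 3], "cns_mpo": [3.0, 3.0],
            "bbb_score": [4.0, 4.0], "neg_logs": [5.0, 5.0],
        }, index=pd.Index(["B", "A"], name="compound_id"))
        assert list(rank(df).index) == ["A", "B"]

    def test_input_order_permutation_invariance(self):
        df = toy_candidates()
        out1 = rank(screen(df, DEFAULT_THRESHOLDS))
        out2 = rank(screen(df.iloc[::-1], DEFAULT_THRESHOLDS))
        assert list(out1.index) == list(out2.index)
        assert list(out1["rank"]) == list(out2["rank"])

    def test_rank_is_a_permutation(self, hr_screen_oracle):
        out = rank(screen(hr_screen_oracle[["cns_mpo", "bbb_score",
                                            "neg_logs", "mpa"]],
                          DEFAULT_THRESHOLDS))
        assert sorted(out["rank"]) == list(range(1, len(out) + 1))

    def test_adding_a_candidate_preserves_relative_order(self):
        base = toy_candidates()
        out_base = rank(screen(base, DEFAULT_THRESHOLDS))
        extra = pd.concat([base, pd.DataFrame({
            "cns_mpo": [5.0], "bbb_score": [5.0], "neg_logs": [4.0],
            "mpa": [50.0]}, index=pd.Index(["Z"], name="compound_id"))])
        out_extra = rank(screen(extra, DEFAULT_THRESHOLDS))
        old = [cid for cid in out_extra.index if cid in base.index]
        assert old == list(out_base.index)


class TestThresholdSet:
    def test_yaml_round_trip_is_exact(self, tmp_path):
        path = tmp_path / "thresholds.yaml"
        DEFAULT_THRESHOLDS.to_yaml(path)
        assert ThresholdSet.from_yaml(path) == DEFAULT_THRESHOLDS

    def test_strict_differs_only_in_mpo_cutoff(self):
        assert STRICT_THRESHOLDS.cns_mpo_min == 4.0
        assert STRICT_THRESHOLDS.herg_max == DEFAULT_THRESHOLDS.herg_max


class TestCompoundScreen:
    def test_transformer_fit_transform(self, hr_screen_oracle):
        est = CompoundScreen(preset="default")
        out = est.fit(None).transform(
            hr_screen_oracle[["cns_mpo", "bbb_score", "neg_logs", "mpa"]])
        assert "rank" in out.columns
        assert est.thresholds_ == DEFAULT_THRESHOLDS

    def test_get_params_round_trip(self):
        est = CompoundScreen(preset="strict")
        assert CompoundScreen(**est.get_params()).preset == "strict"
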