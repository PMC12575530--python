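"""Threshold calibration and the disjunction classifier."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pancad import (
    CaseScores,
    DisjunctionDetector,
    Thresholds,
    calibrate_thresholds,
    classify_case,
    classify_cohort,
)


def scores_frame(cancer_heat, cancer_dp, control_heat, control_dp):
    rows = []
    for i, (h, d) in enumerate(zip(cancer_heat, cancer_dp)):
        rows.append(dict(case_id=f"ca{i}", label="cancer", heatmap_max=h, dp_p90=d))
    for i, (h, d) in enumerate(zip(control_heat, control_dp)):
        rows.append(dict(case_id=f"co{i}", label="control", heatmap_max=h, dp_p90=d))
    return pd.DataFrame(rows)


PAPER_LIKE_THRESHOLDS = Thresholds(heatmap_thr=0.051, dp_thr=0.019)


class TestCalibration:
    def test_mass_cutoff_is_midpoint_keeping_four_of_five(self):
        # brute-force check: any cutoff in (0.1, 0.6) keeps 4/5 above; midpoint 0.35
        df = scores_frame([0.9, 0.8, 0.7, 0.6, 0.1], [0.02] * 5, [0.1, 0.2], [0.01, 0.015])
        thr = calibrate_thresholds(df, target_mass_sensitivity=0.80)
        assert thr.heatmap_thr == pytest.approx(0.35)
        sweep = [
            t for t in np.linspace(0, 1, 2001)
            if np.mean(np.array([0.9, 0.8, 0.7, 0.6, 0.1]) > t) >= 0.8
        ]
        assert max(sweep) == pytest.approx(0.6, abs=1e-3)
        assert 0.1 < thr.heatmap_thr < 0.6

    def test_dp_cutoff_is_max_of_controls(self):
        df = scores_frame([0.9, 0.8], [0.05, 0.06], [0.1] * 3, [0.010, 0.015, 0.019])
        thr = calibrate_thresholds(df)
        assert thr.dp_thr == pytest.approx(0.019)
        # all three controls are negative under strict >
        for d in (0.010, 0.015, 0.019):
            res = classify_case(CaseScores("x", heatmap_max=0.0, dp_p90=d), thr)
            assert "dp" not in res.fired_channels

    def test_empty_or_one_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_thresholds(pd.DataFrame(columns=["label", "heatmap_max", "dp_p90"]))
        df = scores_frame([0.5], [0.02], [], [])
        with pytest.raises(ValueError, match="both classes"):
            calibrate_thresholds(df)

    def test_unattainable_target_reports_achieved_rate(self):
        df = scores_frame([0.0, 0.0], [0.02, 0.02], [0.1], [0.01])
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_thresholds(df)

    @given(
        heat=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=40),
        dp=st.lists(st.floats(0.0, 0.3), min_size=2, max_size=40),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_achieved_rates_meet_targets(self, heat, dp):
        df = scores_frame(heat, [0.02] * len(heat), [0.1] * len(dp), dp)
        thr = calibrate_thresholds(df)
        prov = thr.provenance
        assert prov["achieved_mass_sensitivity"] >= 0.80
        assert prov["achieved_dp_specificity"] == 1.0
        # re-check directly, not just from provenance
        assert np.mean(np.asarray(heat) > thr.heatmap_thr) >= 0.80
        assert np.mean(np.asarray(dp) > thr.dp_thr) == 0.0


class TestClassifyCase:
    def test_positive_via_mass_only(self):
        res = classify_case(
            CaseScores("a", heatmap_max=0.06, dp_p90=0.010), PAPER_LIKE_THRESHOLDS
        )
        assert res.verdict == "positive"
        assert res.fired_channels == ("mass",)

    def test_boundary_equality_is_negative(self):
        res = classify_case(
            CaseScores("b", heatmap_max=0.051, dp_p90=0.019), PAPER_LIKE_THRESHOLDS
        )
        assert res.verdict == "negative"
        assert res.fired_channels == ()

    def test_positive_via_dp_with_dp_localization(self):
        res = classify_case(
            CaseScores("c", heatmap_max=0.02, dp_p90=0.030,
                       dp_segment="body", jump_fraction=0.55),
            PAPER_LIKE_THRESHOLDS,
        )
        assert res.verdict == "positive"
        assert res.fired_channels == ("dp",)
        assert res.localization_source == "dp"
        assert res.segment == "body"

    def test_mass_localization_takes_precedence(self):
        res = classify_case(
            CaseScores("d", heatmap_max=0.9, dp_p90=0.9,
                       mass_segment="head", dp_segment="tail"),
            PAPER_LIKE_THRESHOLDS,
        )
        assert res.localization_source == "mass"
        assert res.segment == "head"

    def test_missing_channel_warns_and_does_not_fire(self):
        with pytest.warns(UserWarning, match="missing heatmap"):
            res = classify_case(
                CaseScores("e", heatmap_max=None, dp_p90=0.5), PAPER_LIKE_THRESHOLDS
            )
        assert res.fired_channels == ("dp",)


class TestClassifyCohort:
    def cohort(self):
        rng = np.random.default_rng(17)
        return scores_frame(
            rng.uniform(0, 1, 20), rng.uniform(0, 0.1, 20),
            rng.uniform(0, 0.5, 20), rng.uniform(0, 0.03, 20),
        )

    def test_combined_true_positives_are_union_of_channels(self):
        df = self.cohort()
        out, tables = classify_cohort(df, PAPER_LIKE_THRESHOLDS)
        mass_tp = set(out[(out["fired_channels"].str.contains("mass"))
                          & (df["label"] == "cancer")]["case_id"])
        dp_tp = set(out[(out["fired_channels"].str.contains("dp"))
                        & (df["label"] == "cancer")]["case_id"])
        comb_tp = set(out[(out["verdict"] == "positive")
                          & (df["label"] == "cancer")]["case_id"])
        assert comb_tp == mass_tp | dp_tp
        assert tables["combined"].tp == len(comb_tp)

    def test_combined_sensitivity_and_specificity_ordering(self):
        _, tables = classify_cohort(self.cohort(), PAPER_LIKE_THRESHOLDS)
        sens = {k: t.tp / t.positives for k, t in tables.items()}
        spec = {k: t.tn / t.negatives for k, t in tables.items()}
        assert sens["combined"] >= max(sens["mass"], sens["dp"])
        assert spec["combined"] <= min(spec["mass"], spec["dp"])

    def test_vacuous_dp_channel_reduces_to_mass_only(self):
        df = self.cohort()
        df["dp_p90"] = 0.0
        out, tables = classify_cohort(df, PAPER_LIKE_THRESHOLDS)
        assert (out["verdict"] == "positive").equals(
            out["fired_channels"].str.contains("mass")
        )
        assert tables["combined"].tp == tables["mass"].tp
        assert tables["combined"].fp == tables["mass"].fp

    def test_duplicate_case_ids_rejected(self):
        df = self.cohort()
        df.loc[1, "case_id"] = df.loc[0, "case_id"]
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort(df, PAPER_LIKE_THRESHOLDS)

    @given(
        dh=st.floats(0.0, 0.5),
        dd=st.floats(0.0, 0.5),
    )
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_raising_thresholds_never_creates_positives(self, dh, dd):
        df = self.cohort()
        base = PAPER_LIKE_THRESHOLDS
        raised = Thresholds(base.heatmap_thr + dh, base.dp_thr + dd)
        v0, _ = classify_cohort(df, base)
        v1, _ = classify_cohort(df, raised)
        flipped = (v0["verdict"] == "negative") & (v1["verdict"] == "positive")
        assert not flipped.any()


class TestModelResults:
    def test_fit_summary_and_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(23)
        df = scores_frame(
            rng.uniform(0.2, 1, 24), rng.uniform(0.02, 0.2, 24),
            rng.uniform(0, 0.5, 26), rng.uniform(0, 0.04, 26),
        )
        fit = DisjunctionDetector.from_dataframe(df).fit()
        text = fit.summary()
        assert "mass-channel threshold" in text and "combined" in text
        p = tmp_path / "thr.json"
        fit.thresholds.to_json(p)
        back = Thresholds.from_json(p)
        assert back.heatmap_thr == fit.thresholds.heatmap_thr
        assert back.dp_thr == fit.thresholds.dp_thr
        ev = fit.evaluate()
        assert set(ev) == {"mass", "dp", "combined"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="finite and nonnegative"):
            Thresholds(heatmap_thr=float("nan"), dp_thr=0.1)
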