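"""Evaluation statistics, each cross-checked against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher, hypergeom

from pancad import (
    ConfusionTable,
    confusion_metrics,
    decision_curve,
    fisher_exact_rxc,
    mcnemar_exact,
    proportion_ci,
    roc_curve,
    stratified_compare,
)

# confusion counts reconstructed from the reported cohort (100 cancers, 104
# controls): mass channel 77/100 sens, 79/104 spec; duct channel 87/100,
# 98/104; combination 96/100, 73/104
MASS = ConfusionTable(tp=77, fp=25, fn=23, tn=79)
DUCT = ConfusionTable(tp=87, fp=6, fn=13, tn=98)
COMBINED = ConfusionTable(tp=96, fp=31, fn=4, tn=73)


class TestConfusionMetrics:
    def test_combined_table_reproduces_reported_percentages(self):
        m = confusion_metrics(COMBINED)
        assert m["sensitivity"].as_percent()[0] == 96.0
        assert m["specificity"].as_percent()[0] == 70.2
        assert m["ppv"].as_percent()[0] == 75.6
        assert m["npv"].as_percent()[0] == 94.8

    def test_perfect_classifier_scores_100_everywhere(self):
        m = confusion_metrics(ConfusionTable(tp=7, fp=0, fn=0, tn=9))
        for est in m.values():
            assert est.estimate == 1.0

    def test_zero_denominator_flagged_not_zero(self):
        m = confusion_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
        assert not m["sensitivity"].defined
        assert math.isnan(m["sensitivity"].estimate)
        assert m["specificity"].defined

    def test_wald_ci_clipped_to_unit_interval(self):
        est = proportion_ci(5, 6)  # 83.3% with a wide interval
        assert est.ci_high == 1.0
        assert est.as_percent() == (83.3, 53.5, 100.0)

    def test_alternative_ci_methods_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(77, 100), (98, 104), (4, 6)]:
            # Clopper-Pearson has no z convention and must agree exactly;
            # Wilson differs only through our reporting z of 1.96 vs 1.959964
            est = proportion_ci(k, n, method="clopper-pearson")
            lo, hi = sm.proportion_confint(k, n, alpha=0.05, method="beta")
            assert est.ci_low == pytest.approx(lo, abs=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9)
            est = proportion_ci(k, n, method="wilson")
            lo, hi = sm.proportion_confint(k, n, alpha=0.05, method="wilson")
            assert est.ci_low == pytest.approx(lo, abs=5e-4)
            assert est.ci_high == pytest.approx(hi, abs=5e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=0)


class TestMcNemar:
    @pytest.mark.parametrize(
        "b, c, expected",
        [(4, 4, 1.0), (0, 0, 1.0), (5, 0, 0.0625), (0, 5, 0.0625)],
    )
    def test_closed_form_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    def test_against_statsmodels_exact(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(3, 9), (1, 1), (7, 2), (0, 4), (10, 15)]:
            ours = mcnemar_exact(b, c)
            theirs = sm.mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    @given(b=st.integers(0, 30), c=st.integers(0, 30))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_in_unit_interval(self, b, c):
        p = mcnemar_exact(b, c)
        assert p == mcnemar_exact(c, b)
        assert 0.0 < p <= 1.0
        if b == c:
            assert p == 1.0


class TestFisherRxC:
    def test_two_by_two_matches_scipy(self):
        tables = [
            [[1, 0], [0, 1]],
            [[2, 2], [2, 2]],
            [[5, 1], [2, 7]],
            [[10, 2], [3, 9]],
            [[0, 5], [5, 0]],
            [[3, 0], [0, 0]],
        ]
        for t in tables:
            _, expected = scipy_fisher(np.asarray(t))
            assert fisher_exact_rxc(t) == pytest.approx(expected, abs=1e-9)

    def test_two_by_two_matches_hypergeometric_closed_form(self):
        # tail sum of the conditional hypergeometric, the textbook definition
        t = [[5, 1], [2, 7]]
        n1, n2 = 6, 9
        k = 7  # column-1 margin
        probs = [hypergeom.pmf(a, n1 + n2, n1, k) for a in range(max(0, k - n2), min(n1, k) + 1)]
        obs = hypergeom.pmf(5, n1 + n2, n1, k)
        expected = sum(p for p in probs if p <= obs * (1 + 1e-9))
        assert fisher_exact_rxc(t) == pytest.approx(expected, abs=1e-12)

    def test_identity_table(self):
        assert fisher_exact_rxc([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[2, 2], [2, 2]]) == pytest.approx(1.0)
        assert fisher_exact_rxc([[3, 1], [3, 1], [3, 1]]) == pytest.approx(1.0)

    def test_four_by_two_location_tables(self):
        # detected/missed counts by tumor location, per channel
        assert fisher_exact_rxc([[5, 1], [35, 8], [26, 7], [11, 7]]) == pytest.approx(
            0.360, abs=5e-4
        )
        assert fisher_exact_rxc([[4, 2], [35, 8], [31, 2], [17, 1]]) == pytest.approx(
            0.119, abs=5e-4
        )
        assert fisher_exact_rxc([[5, 1], [41, 2], [32, 1], [18, 0]]) == pytest.approx(
            0.362, abs=5e-4
        )

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_rxc([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="R x 2"):
            fisher_exact_rxc([[1, 2, 3], [4, 5, 6]])


class TestROC:
    def test_perfect_separation(self):
        *_, auc = roc_curve([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_sign_flip_complements_auc(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1, 50)
        y = rng.random(50) < 0.4
        *_, auc = roc_curve(s, y)
        *_, auc_neg = roc_curve(-s, y)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_matches_sklearn_with_ties(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        s = np.round(rng.uniform(0, 1, 200), 2)  # heavy ties
        y = rng.random(200) < 0.5
        *_, auc = roc_curve(s, y)
        assert auc == pytest.approx(sk.roc_auc_score(y, s), abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, 4000)
        y = rng.random(4000) < 0.5
        *_, auc = roc_curve(s, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_endpoints_and_monotone(self):
        fpr, tpr, _, _ = roc_curve([0.3, 0.3, 0.7], [False, True, True])
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], [True, True])


class TestDecisionCurve:
    def test_perfect_model_net_benefit_is_prevalence(self):
        t = ConfusionTable(tp=40, fp=0, fn=0, tn=60)
        nb = decision_curve({"perfect": t})
        assert np.allclose(nb.curves["perfect"], 0.4)

    def test_small_pt_limit_approaches_tp_fraction(self):
        nb = decision_curve({"m": COMBINED}, pt_grid=np.array([0.001]))
        assert nb.curves["m"][0] == pytest.approx(COMBINED.tp / COMBINED.n, abs=1e-3)

    def test_treat_none_is_zero_and_curves_finite(self):
        nb = decision_curve({"mass": MASS, "combined": COMBINED})
        assert np.all(nb.curves["treat_none"] == 0.0)
        for c in nb.curves.values():
            assert np.all(np.isfinite(c))

    def test_combined_beats_mass_at_low_threshold(self):
        nb = decision_curve({"mass": MASS, "combined": COMBINED})
        i = np.argmin(np.abs(nb.threshold_probabilities - 0.1))
        assert nb.curves["combined"][i] > nb.curves["mass"][i]

    def test_crossing_with_treat_all_matches_algebra(self):
        # NB_model(pt) = NB_all(pt) at odds = (tp/N - prev) / (fp/N - (1-prev))
        t = COMBINED
        n, prev = t.n, t.prevalence
        odds = (t.tp / n - prev) / (t.fp / n - (1 - prev))
        pt_cross = odds / (1 + odds)
        nb = decision_curve({"m": t})
        d = nb.curves["m"] - nb.curves["treat_all"]
        sign_change = np.nonzero(np.diff(np.sign(d)))[0]
        assert len(sign_change) == 1
        lo = nb.threshold_probabilities[sign_change[0]]
        hi = nb.threshold_probabilities[sign_change[0] + 1]
        assert lo <= pt_cross <= hi

    def test_invalid_grid_and_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="strictly in"):
            decision_curve({"m": MASS}, pt_grid=np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="cohort size"):
            decision_curve({"a": MASS, "b": ConfusionTable(tp=1, fp=1, fn=1, tn=1)})


class TestStratifiedCompare:
    LOCATIONS = {
        "head_uncinate": ConfusionTable(tp=5, fp=0, fn=1, tn=0),
        "head_other": ConfusionTable(tp=35, fp=0, fn=8, tn=0),
        "body": ConfusionTable(tp=26, fp=0, fn=7, tn=0),
        "tail": ConfusionTable(tp=11, fp=0, fn=7, tn=0),
    }

    def test_delegates_to_fisher(self):
        res = stratified_compare(self.LOCATIONS, "sensitivity")
        assert res["p_value"] == pytest.approx(
            fisher_exact_rxc([[5, 1], [35, 8], [26, 7], [11, 7]]), abs=1e-12
        )
        assert not res["significant"]

    def test_identical_strata_give_p_one(self):
        t = ConfusionTable(tp=8, fp=2, fn=2, tn=8)
        res = stratified_compare({"a": t, "b": t}, "sensitivity")
        assert res["p_value"] == pytest.approx(1.0)

    def test_bonferroni_alpha(self):
        res = stratified_compare(self.LOCATIONS, "sensitivity", bonferroni_k=4)
        assert res["alpha"] == pytest.approx(0.0125)

    def test_undefined_stratum_dropped_with_warning(self):
        tables = dict(self.LOCATIONS)
        tables["empty"] = ConfusionTable(tp=0, fp=3, fn=0, tn=2)
        with pytest.warns(UserWarning, match="dropped"):
            res = stratified_compare(tables, "sensitivity")
        assert "empty" not in res["strata"]

    def test_fewer_than_two_strata_rejected(self):
        with pytest.raises(ValueError, match="two strata"):
            stratified_compare({"only": ConfusionTable(tp=1, fp=0, fn=1, tn=0)})
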