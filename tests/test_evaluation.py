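"""Metrics and threshold analytics, checked against enumeration oracles."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from sepsiswatch import (
    auc_continuous,
    binary_auc,
    coefficient_of_variation,
    confusion_report,
    fp_per_day_from_rate,
    incremental_tp,
    monthly_performance,
    replay_calendar,
    simulate_cohort,
    sirs_alerts,
    sirs_rule,
    threshold_for_fp_budget,
    threshold_for_sensitivity,
    threshold_max_binary_auc,
)
from sepsiswatch.cohort import CohortConfig, table1_features


def pairwise_auc(scores, labels):
    """Brute-force concordance over all (septic, non-septic) pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


def random_instances(n_instances, max_n=200, seed=0, tie_prone=True):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(10, max_n + 1))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if tie_prone and rng.random() < 0.5:
            s = rng.integers(0, 6, size=n).astype(float) / 5.0  # heavy ties
        else:
            s = rng.random(n)
        yield s, y


class TestAucContinuous:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),          # perfect separation
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),          # all ties
        ([0.8, 0.3, 0.5, 0.2, 0.3], [1, 1, 0, 0, 0], 4.5 / 6),  # enumerated pairs
    ])
    def test_enumerated_examples(self, scores, labels, expected):
        assert auc_continuous(scores, labels) == pytest.approx(expected, abs=1e-15)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_continuous([0.1, 0.2], [1, 1])

    def test_matches_pairwise_and_sklearn(self):
        for s, y in random_instances(30, max_n=80, seed=5):
            ours = auc_continuous(s, y)
            assert ours == pytest.approx(pairwise_auc(s, y), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_binary_alert_score_equals_binary_auc(self):
        """A 0/1 alert treated as a score has concordance (sens+spec)/2 exactly."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 60
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                continue
            alert = (rng.random(n) < 0.4).astype(int)
            rep = confusion_report(alert.astype(float), y, 0.5, days=1.0)
            assert auc_continuous(alert.astype(float), y) == pytest.approx(
                binary_auc(rep.sensitivity, rep.fpr), abs=1e-15)


class TestBinaryAuc:
    @pytest.mark.parametrize("sens,fpr,expected", [
        (0.543, 0.031, 0.756),   # triage-nurse operating point
        (0.216, 0.004, 0.606),   # SIRS-derived rule operating point
        (1.0, 0.0, 1.0),
    ])
    def test_operating_points(self, sens, fpr, expected):
        assert binary_auc(sens, fpr) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binary_auc(1.2, 0.0)


class TestConfusionReport:
    def test_always_alert(self, toy_scores):
        s, y = toy_scores
        rep = confusion_report(s, y, 0.0, days=1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_never_alert(self, toy_scores):
        s, y = toy_scores
        rep = confusion_report(s, y, 2.0, days=1.0)
        assert rep.sensitivity == 0.0
        assert rep.npv == pytest.approx(1 - y.mean())
        assert math.isnan(rep.ppv)

    def test_hand_enumerated_table(self):
        s = np.array([0.9, 0.6, 0.4, 0.1])
        y = np.array([1, 0, 1, 0])
        rep = confusion_report(s, y, 0.5, days=2.0)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (1, 1, 1, 1)
        assert rep.sensitivity == 0.5 and rep.fpr == 0.5
        assert rep.ppv == 0.5 and rep.fp_per_day == 0.5

    def test_counts_sum_and_ppv_identity(self):
        for s, y in random_instances(20, max_n=120, seed=7):
            rep = confusion_report(s, y, 0.5, days=3.0)
            assert rep.n == len(s)
            if rep.tp + rep.fp:
                assert rep.ppv * (rep.tp + rep.fp) == pytest.approx(rep.tp, abs=1e-9)

    def test_nonpositive_days(self, toy_scores):
        with pytest.raises(ValueError, match="days"):
            confusion_report(*toy_scores, 0.5, days=0.0)


class TestFpPerDay:
    def test_published_reconciliations(self):
        # threshold tuned to the 15 alerts/day budget: printed 15.00
        assert fp_per_day_from_rate(0.073, 93_421, 456) == pytest.approx(14.96, abs=0.01)
        # deployed 0.05 threshold: printed 9.64
        assert fp_per_day_from_rate(0.047, 93_421, 456) == pytest.approx(9.63, abs=0.01)
        assert fp_per_day_from_rate(0.0, 1000, 10) == 0.0

    def test_bad_days(self):
        with pytest.raises(ValueError):
            fp_per_day_from_rate(0.1, 100, 0)


class TestThresholdSearches:
    def test_target_one_forces_min_septic_score(self, toy_scores):
        s, y = toy_scores
        assert threshold_for_sensitivity(s, y, 1.0) == 0.2

    def test_sensitivity_enumerated(self, toy_scores):
        s, y = toy_scores
        assert threshold_for_sensitivity(s, y, 0.66) == 0.7   # sens 2/3
        assert threshold_for_sensitivity(s, y, 0.67) == 0.2   # forced to sens 1

    def test_budget_enumerated(self):
        s = np.array([0.8, 0.6, 0.4, 0.9])
        y = np.array([0, 0, 0, 1])
        assert threshold_for_fp_budget(s, y, 1.0, days=1.0) == 0.8
        assert threshold_for_fp_budget(s, y, 100.0, days=1.0) == 0.4  # min score
        assert threshold_for_fp_budget(s, y, 0.0, days=1.0) == 0.9    # zero-FP

    def test_max_binary_auc_enumerated(self, toy_scores):
        s, y = toy_scores
        t = threshold_max_binary_auc(s, y)
        assert t == 0.7
        rep = confusion_report(s, y, t, days=1.0)
        assert rep.binary_auc == pytest.approx((2 / 3 + 1.0) / 2)

    def test_max_binary_auc_separable_and_inverted(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert threshold_max_binary_auc(s, y) == 0.8  # lowest septic score
        y_inv = 1 - y
        t = threshold_max_binary_auc(s, y_inv)
        rep = confusion_report(s, y_inv, t, days=1.0)
        assert rep.binary_auc == pytest.approx(0.5)

    def test_agree_with_exhaustive_search(self):
        """All three searches match brute force over every candidate cutpoint."""
        for s, y in random_instances(25, max_n=150, seed=11):
            cands = np.concatenate([np.unique(s), [np.inf]])
            pos, neg = s[y == 1], s[y == 0]
            sens = np.array([(pos >= t).mean() for t in cands])
            fp = np.array([(neg >= t).sum() for t in cands])
            days = 2.0

            target = 0.8
            feasible = cands[sens >= target]
            assert threshold_for_sensitivity(s, y, target) == feasible.max()

            budget = float(np.median(fp)) / days
            ok = cands[fp / days <= budget]
            expected = ok.min()
            got = threshold_for_fp_budget(s, y, budget, days)
            # the search returns an observed score; +inf only when required
            assert got == (expected if np.isfinite(expected) else np.inf)

            j = (sens + 1 - fp / max(neg.size, 1)) / 2
            best = j.max()
            got_t = threshold_max_binary_auc(s, y)
            idx = np.searchsorted(cands, got_t)
            assert j[idx] == pytest.approx(best, abs=1e-12)


class TestIncrementalTp:
    def test_identical_systems(self):
        y = [1, 1, 0]
        m = [1, 0, 1]
        assert incremental_tp(m, m, y) == (0, 0, 1)

    def test_hand_enumeration(self):
        y = [1, 1, 1, 0]
        model = [1, 1, 0, 1]
        screen = [0, 1, 1, 0]
        assert incremental_tp(model, screen, y) == (1, 1, 1)

    def test_screen_all_zero(self):
        y = [1, 1, 0, 1]
        model = [1, 0, 1, 1]
        model_only, screen_only, both = incremental_tp(model, [0, 0, 0, 0], y)
        assert screen_only == 0 and both == 0 and model_only == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            incremental_tp([1], [1, 0], [1, 0])


class TestSirsRule:
    def test_all_components_met(self):
        enc = {"temp_c": 39.0, "hr": 100.0, "rr": 22.0, "wbc_k": 15.0}
        for k in range(1, 5):
            assert sirs_rule(enc, k=k) == 1

    def test_all_missing_no_alert(self):
        enc = {"temp_c": None, "hr": None, "rr": None, "wbc_k": None}
        assert sirs_rule(enc, k=1) == 0

    def test_missing_counts_unsatisfied(self):
        enc = {"temp_c": 37.0, "hr": 95.0, "rr": 21.0, "wbc_k": None}
        assert sirs_rule(enc, k=2) == 1
        assert sirs_rule(enc, k=3) == 0

    def test_low_wbc_and_hypothermia_count(self):
        enc = {"temp_c": 35.0, "hr": 60.0, "rr": 12.0, "wbc_k": 3.0}
        assert sirs_rule(enc, k=2) == 1

    def test_vectorized_matches_scalar(self):
        df = pd.DataFrame({
            "temp_c": [39.0, 36.5, np.nan, 35.0],
            "hr": [100.0, 91.0, 95.0, np.nan],
            "rr": [22.0, 10.0, 21.0, 25.0],
            "wbc_k": [15.0, np.nan, np.nan, 3.0],
        })
        vec = sirs_alerts(df, k=2)
        scalar = [sirs_rule(row, k=2) for _, row in df.iterrows()]
        assert list(vec) == scalar


class TestCoefficientOfVariation:
    def test_simple_values(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_published_auc_column(self, printed):
        cv = coefficient_of_variation(printed.table3["cont_auc"])
        assert round(cv, 3) == 0.014

    def test_errors(self):
        with pytest.raises(ValueError, match="2 values"):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])


@pytest.fixture()
def two_identical_months():
    base = pd.DataFrame({
        "month_index": [0] * 6,
        "sepsis": [1, 1, 0, 0, 0, 0],
    })
    scores = np.array([0.9, 0.4, 0.6, 0.2, 0.1, 0.05])
    flags = np.array([1, 0, 0, 0, 1, 0])
    second = base.assign(month_index=1)
    df = pd.concat([base, second], ignore_index=True)
    return df, np.tile(scores, 2), np.tile(flags, 2)


class TestMonthlyPerformance:
    def test_identical_months_have_zero_cv(self, two_identical_months):
        df, scores, flags = two_identical_months
        perf = monthly_performance(df, scores, 0.5, flags, month_days=[30, 30])
        assert (perf.summary.loc["cv"].dropna() == 0.0).all()
        assert perf.rows["sepsis"].sum() == df["sepsis"].sum()

    def test_single_class_month_excluded_from_summary(self):
        df = pd.DataFrame({"month_index": [0, 0, 1, 1],
                           "sepsis": [1, 0, 0, 0]})
        scores = np.array([0.9, 0.1, 0.5, 0.2])
        perf = monthly_performance(df, scores, 0.5, [0, 0, 0, 0], month_days=[30, 30])
        assert math.isnan(perf.rows.loc[1, "cont_auc"])
        assert perf.summary.loc["min", "cont_auc"] == 1.0  # only month 0 counted

    def test_replayed_calendar_counts_and_pooled_totals(self, calendar_cohort, printed):
        scores = np.asarray(calendar_cohort["hr"].fillna(0.0), float)
        perf = monthly_performance(calendar_cohort, scores, 100.0,
                                   calendar_cohort["nurse_flag"],
                                   month_days=printed.month_days)
        assert list(perf.rows["sepsis"]) == list(printed.table3["sepsis"])
        assert list(perf.rows["encounters"]) == list(printed.table3["encounters"])
        assert perf.rows["encounters"].sum() == 93_773

    def test_month_outside_calendar(self):
        df = pd.DataFrame({"month_index": [0, 3], "sepsis": [1, 0]})
        with pytest.raises(ValueError, match="calendar"):
            monthly_performance(df, [0.5, 0.5], 0.5, [0, 0], month_days=[30])
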