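"""Alert operating-point metrics, threshold searches, and monthly stability.

This module contains the evaluation side of the screening pipeline: ROC
concordance for the continuous sepsis-probability score, 2x2 operating-point
reports for a binary alert (sensitivity, specificity, PPV, NPV, false
positives per day), threshold searches against clinical targets (a
sensitivity floor or an alert-burden budget), incremental true-positive
accounting against a concurrent human screen, a configurable SIRS-style
rule comparator, and per-calendar-month performance with coefficient-of-
variation stability summaries.

Conventions
-----------
* An alert fires when ``score >= threshold`` (ties alert).
* Candidate thresholds are the unique observed scores plus ``+inf``; no
  interpolation between observed scores is performed.
* AUC is pairwise concordance: the probability that a randomly chosen
  septic encounter scores above a randomly chosen non-septic one, with
  ties counted 1/2.  For a single-threshold binary alert this reduces to
  ``(sensitivity + specificity) / 2``.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "AlertReport",
    "MonthlyPerformance",
    "auc_continuous",
    "binary_auc",
    "confusion_report",
    "fp_per_day_from_rate",
    "threshold_for_sensitivity",
    "threshold_for_fp_budget",
    "threshold_max_binary_auc",
    "incremental_tp",
    "sirs_rule",
    "sirs_alerts",
    "monthly_performance",
    "coefficient_of_variation",
    "round_half_away",
    "SIRS_DEFAULTS",
]

#: SIRS component cutoffs: abnormal temperature, tachycardia, tachypnea,
#: abnormal white count.  Units: Celsius, min^-1, min^-1, 10^3/uL.
SIRS_DEFAULTS: Mapping[str, float] = {
    "temp_high": 38.0,
    "temp_low": 36.0,
    "hr_gt": 90.0,
    "rr_gt": 20.0,
    "wbc_high": 12.0,
    "wbc_low": 4.0,
}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(bool)


@dataclass(frozen=True)
class AlertReport:
    """Operating-point metrics for a binary alert at one threshold.

    ``ppv`` is NaN when the alert never fires; ``fp_per_day`` uses the
    calendar length supplied to :func:`confusion_report`.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fpr: float
    ppv: float
    npv: float
    binary_auc: float
    fp_per_day: float
    days: float
    incremental_tp_model: int | None = None
    incremental_tp_screen: int | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def auc_continuous(scores, labels) -> float:
    """Concordance AUC of a continuous score (ties count 1/2).

    Equals the trapezoidal area under the empirical ROC curve; computed via
    midranks (Mann-Whitney) so it is O(n log n) and exact under ties.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def binary_auc(sensitivity: float, fpr: float) -> float:
    """Concordance AUC of a single-threshold binary alert: (sens + spec) / 2."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("sensitivity and fpr must lie in [0, 1]")
    return (sensitivity + (1.0 - fpr)) / 2.0


def fp_per_day_from_rate(fpr: float, n_negative: int, days: float) -> float:
    """Daily false-positive alert burden implied by a false positive rate."""
    if days <= 0:
        raise ValueError("days must be positive")
    if fpr < 0 or n_negative < 0:
        raise ValueError("fpr and n_negative must be non-negative")
    return fpr * n_negative / days


def confusion_report(scores, labels, threshold: float, days: float) -> AlertReport:
    """Full operating-point report for alerting at ``score >= threshold``."""
    if days <= 0:
        raise ValueError("days must be positive")
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("confusion_report requires both classes present")
    alert = s >= threshold
    tp = int(np.sum(alert & y))
    fp = int(np.sum(alert & ~y))
    fn = int(np.sum(~alert & y))
    tn = int(np.sum(~alert & ~y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    fpr = fp / (fp + tn)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return AlertReport(
        threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, fpr=fpr, ppv=ppv, npv=npv,
        binary_auc=binary_auc(sens, fpr),
        fp_per_day=fp / days,
        days=float(days),
    )


def _split_sorted(scores, labels):
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return np.sort(s[y]), np.sort(s[~y])


def threshold_for_sensitivity(scores, labels, target: float) -> float:
    """Largest candidate threshold whose sensitivity is >= ``target``.

    Candidate thresholds are the unique observed scores; sensitivity is
    non-decreasing as the threshold is lowered, so the answer is the k-th
    largest septic score with ``k = ceil(target * n_septic)``.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    pos, _ = _split_sorted(scores, labels)
    k = math.ceil(target * pos.size)
    return float(pos[pos.size - k])


def threshold_for_fp_budget(scores, labels, max_fp_per_day: float, days: float) -> float:
    """Smallest candidate threshold whose false-positive burden meets a budget.

    Because false positives shrink monotonically as the threshold rises, the
    smallest admissible threshold maximizes sensitivity within the budget.
    Returns ``+inf`` when even alerting on no observed score would be needed
    (never happens for a positive budget unless all scores are negative class
    and tied at the top -- the ``+inf`` candidate always satisfies budget 0).
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if max_fp_per_day < 0:
        raise ValueError("budget must be non-negative")
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    neg = np.sort(s[~y])
    cands = np.unique(s)
    # false positives when alerting at >= t: negatives with score >= t
    fp_counts = neg.size - np.searchsorted(neg, cands, side="left")
    ok = fp_counts / days <= max_fp_per_day
    if ok.any():
        return float(cands[np.argmax(ok)])
    return float("inf")


def threshold_max_binary_auc(scores, labels) -> float:
    """Candidate threshold maximizing (sensitivity + specificity) / 2.

    Ties are broken toward the higher threshold (fewer alerts); on perfectly
    separated data this returns the lowest septic score.
    """
    pos, neg = _split_sorted(scores, labels)
    cands = np.unique(np.concatenate([pos, neg]))
    sens = (pos.size - np.searchsorted(pos, cands, side="left")) / pos.size
    fpr = (neg.size - np.searchsorted(neg, cands, side="left")) / neg.size
    j = (sens + 1.0 - fpr) / 2.0
    best = j.max()
    return float(cands[np.nonzero(j >= best - 1e-15)[0][-1]])


def incremental_tp(model_alerts, screen_flags, labels) -> tuple[int, int, int]:
    """Septic encounters caught by the model alone, the screen alone, or both.

    This is the incremental true-positive accounting used to compare an
    automated alert with a concurrent triage-nurse screen: among septic
    encounters, how many did each system contribute that the other missed?
    """
    m = np.asarray(model_alerts).astype(bool)
    f = np.asarray(screen_flags).astype(bool)
    y = _as_binary(labels)
    if not (m.shape == f.shape == y.shape):
        raise ValueError("model_alerts, screen_flags and labels must have equal length")
    model_only = int(np.sum(y & m & ~f))
    screen_only = int(np.sum(y & ~m & f))
    both = int(np.sum(y & m & f))
    return model_only, screen_only, both


def _sirs_count(temp_c, hr, rr, wbc_k, params: Mapping[str, float]) -> np.ndarray:
    """Vectorized count of satisfied SIRS components; missing = unsatisfied."""
    t = np.asarray(temp_c, dtype=float)
    h = np.asarray(hr, dtype=float)
    r = np.asarray(rr, dtype=float)
    w = np.asarray(wbc_k, dtype=float)
    with np.errstate(invalid="ignore"):
        c_temp = (t > params["temp_high"]) | (t < params["temp_low"])
        c_hr = h > params["hr_gt"]
        c_rr = r > params["rr_gt"]
        c_wbc = (w > params["wbc_high"]) | (w < params["wbc_low"])
    comps = [np.where(np.isnan(v), False, c) for v, c in
             ((t, c_temp), (h, c_hr), (r, c_rr), (w, c_wbc))]
    return np.sum(comps, axis=0)


def sirs_rule(encounter: Mapping, k: int = 2,
              rule_params: Mapping[str, float] | None = None) -> int:
    """k-of-4 SIRS-style alert for one encounter.

    Components: temperature > 38 or < 36 C, heart rate > 90, respiratory
    rate > 20, WBC > 12 or < 4 (10^3/uL).  A missing component counts as
    unsatisfied.  Returns 1 when at least ``k`` components are met.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must lie in 1..4")
    params = dict(SIRS_DEFAULTS, **(rule_params or {}))

    def _get(key):
        v = encounter.get(key) if hasattr(encounter, "get") else encounter[key]
        return float("nan") if v is None else float(v)

    count = _sirs_count([_get("temp_c")], [_get("hr")], [_get("rr")],
                        [_get("wbc_k")], params)[0]
    return int(count >= k)


def sirs_alerts(encounters: pd.DataFrame, k: int = 2,
                rule_params: Mapping[str, float] | None = None) -> np.ndarray:
    """Vectorized :func:`sirs_rule` over a cohort table."""
    if not 1 <= k <= 4:
        raise ValueError("k must lie in 1..4")
    params = dict(SIRS_DEFAULTS, **(rule_params or {}))
    count = _sirs_count(encounters["temp_c"], encounters["hr"],
                        encounters["rr"], encounters["wbc_k"], params)
    return (count >= k).astype(int)


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation: SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / mean)


@dataclass(frozen=True)
class MonthlyPerformance:
    """Per-month screening metrics plus min/max/CV stability summary.

    ``rows`` has one record per month; ``summary`` has index min/max/cv.
    Months where a metric is undefined (e.g., AUC in a month with a single
    class) hold NaN and are excluded from that column's summary.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "rows": self.rows.reset_index().to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="index"),
        }


def monthly_performance(encounters: pd.DataFrame, scores, threshold: float,
                        screen_flags, month_days: Sequence[float]) -> MonthlyPerformance:
    """Month-by-month alert and screen performance with stability summary.

    Parameters
    ----------
    encounters
        Cohort table with ``month_index`` (0-based) and ``sepsis`` columns.
    scores
        Continuous model scores aligned with ``encounters``.
    threshold
        Alert cutoff applied as ``score >= threshold``.
    screen_flags
        Concurrent binary screen indicator (e.g., the triage-nurse flag).
    month_days
        Calendar length in days of each month index; its length fixes the
        number of months reported.
    """
    y = _as_binary(encounters["sepsis"])
    s = np.asarray(scores, dtype=float)
    flags = np.asarray(screen_flags).astype(bool)
    month = np.asarray(encounters["month_index"])
    n_months = len(month_days)
    if month.min() < 0 or month.max() >= n_months:
        raise ValueError("encounter month_index outside the supplied calendar")

    records = []
    for m in range(n_months):
        sel = month == m
        days = float(month_days[m])
        ym, sm, fm = y[sel], s[sel], flags[sel]
        n = int(sel.sum())
        n_sep = int(ym.sum())
        rec = {
            "month": m,
            "encounters": n,
            "per_day": n / days,
            "sepsis": n_sep,
            "rate": n_sep / n if n else float("nan"),
        }
        both_classes = 0 < n_sep < n
        rec["cont_auc"] = auc_continuous(sm, ym) if both_classes else float("nan")
        for prefix, alert in (("alert", sm >= threshold), ("screen", fm)):
            if both_classes:
                tp = int(np.sum(alert & ym))
                fp = int(np.sum(alert & ~ym))
                sens = tp / n_sep
                fpr = fp / (n - n_sep)
                rec[f"{prefix}_sens"] = sens
                rec[f"{prefix}_fpr"] = fpr
                rec[f"{prefix}_fp_per_day"] = fp / days
                rec[f"{prefix}_auc"] = binary_auc(sens, fpr)
            else:
                for suffix in ("sens", "fpr", "fp_per_day", "auc"):
                    rec[f"{prefix}_{suffix}"] = float("nan")
        records.append(rec)

    rows = pd.DataFrame.from_records(records).set_index("month")
    metric_cols = [c for c in rows.columns if c not in ("encounters", "sepsis")]
    summary = {}
    for col in metric_cols:
        v = rows[col].dropna().to_numpy()
        summary[col] = {
            "min": v.min() if v.size else float("nan"),
            "max": v.max() if v.size else float("nan"),
            "cv": coefficient_of_variation(v)
            if v.size >= 2 and v.mean() != 0 else float("nan"),
        }
    summary_df = pd.DataFrame(summary).reindex(["min", "max", "cv"])
    return MonthlyPerformance(rows=rows, summary=summary_df)
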