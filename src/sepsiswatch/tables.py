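"""Published operating characteristics of the validation study, machine-readable.

The package ships the printed summary tables of a 15-month prospective ED
sepsis-alert validation (93,773 encounters, 352 with severe sepsis or septic
shock) as a versioned JSON fixture:

* per-class medians, quartiles and first-hour availability of the candidate
  features (used to calibrate the synthetic cohort generator),
* the threshold-sweep table of alert operating points (sensitivity, FPR,
  binary AUC, PPV, NPV, alerts/day, incremental true positives), and
* month-by-month performance with min/max/CV stability rows.

:func:`consistency_audit` recomputes every quantity in those tables that is
an arithmetic function of other printed numbers (binary-AUC identity,
pooled prevalence, CV rows, reconstructed overall sensitivity, alert-burden
reconciliations) and reports agreement, which both validates the fixture
transcription and exercises the evaluation code against published values.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from . import evaluation as ev

__all__ = [
    "PrintedTables",
    "AuditCheck",
    "load_printed_tables",
    "consistency_audit",
    "reconstruct_overall_sensitivity",
]


@dataclass(frozen=True)
class PrintedTables:
    """In-memory form of the shipped study-results fixture."""

    table1_continuous: Mapping[str, Mapping[str, Mapping[str, float]]]
    table1_binary: Mapping[str, Mapping[str, float]]
    table2: pd.DataFrame
    table3: pd.DataFrame
    table3_summary: Mapping[str, Mapping[str, float]]
    month_days: tuple[int, ...]
    constants: Mapping[str, float]
    notes: tuple[str, ...]

    def to_json_dict(self) -> dict:
        """Serialize back to the on-disk fixture layout (lossless)."""
        cols = ["label"] + [c for c in self.table3.columns]
        return {
            "version": 1,
            "notes": list(self.notes),
            "constants": dict(self.constants),
            "table1": {
                "continuous": {k: {c: dict(v) for c, v in spec.items()}
                               for k, spec in self.table1_continuous.items()},
                "binary": {k: dict(v) for k, v in self.table1_binary.items()},
            },
            "table2": self.table2.reset_index().to_dict(orient="records"),
            "table3": {
                "columns": cols,
                "month_days": list(self.month_days),
                "months": self.table3.reset_index().values.tolist(),
                "summary": {k: dict(v) for k, v in self.table3_summary.items()},
            },
        }


def _from_json_dict(raw: Mapping) -> PrintedTables:
    t2 = pd.DataFrame(raw["table2"]).set_index("label")
    t3_raw = raw["table3"]
    t3 = pd.DataFrame(t3_raw["months"], columns=t3_raw["columns"]).set_index("label")
    return PrintedTables(
        table1_continuous=raw["table1"]["continuous"],
        table1_binary=raw["table1"]["binary"],
        table2=t2,
        table3=t3,
        table3_summary=t3_raw["summary"],
        month_days=tuple(t3_raw["month_days"]),
        constants=raw["constants"],
        notes=tuple(raw["notes"]),
    )


def load_printed_tables() -> PrintedTables:
    """Load the packaged study-results fixture."""
    text = resources.files("sepsiswatch.data").joinpath("printed_tables.json").read_text()
    return _from_json_dict(json.loads(text))


def reconstruct_overall_sensitivity(tables: PrintedTables | None = None) -> float:
    """Pooled alert sensitivity (%) rebuilt from monthly rows.

    Each month's true-positive count is recovered as
    ``round(monthly sensitivity x monthly sepsis count)``; the pooled
    sensitivity is the summed true positives over total septic encounters.
    """
    t = tables or load_printed_tables()
    tp = sum(int(round(s / 100.0 * n))
             for s, n in zip(t.table3["model_sens_pct"], t.table3["sepsis"]))
    return 100.0 * tp / t.table3["sepsis"].sum()


@dataclass(frozen=True)
class AuditCheck:
    """One arithmetic cross-check of the printed tables."""

    name: str
    expected: float
    computed: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance

    def __str__(self) -> str:
        flag = "ok " if self.passed else "FAIL"
        return (f"[{flag}] {self.name}: expected {self.expected:g}, "
                f"computed {self.computed:g} (tol {self.tolerance:g})")


def consistency_audit(tables: PrintedTables | None = None) -> list[AuditCheck]:
    """Recompute every printed quantity that follows from other printed numbers.

    Exact identities (count sums, the binary-AUC identity, CV rows computed
    from the printed monthly values) carry tolerances at the print precision;
    reconciliations whose inputs are themselves rounded (alerts/day from a
    FPR printed to one decimal) carry correspondingly wider tolerances.
    """
    t = tables or load_printed_tables()
    c = t.constants
    checks: list[AuditCheck] = []

    # Cohort size identities.
    checks.append(AuditCheck(
        "total encounters = non-septic + septic",
        c["total_encounters"],
        c["nonseptic_encounters"] + c["septic_encounters"], 0))
    checks.append(AuditCheck(
        "monthly encounter counts sum to total",
        c["total_encounters"], float(t.table3["encounters"].sum()), 0))
    checks.append(AuditCheck(
        "monthly sepsis counts sum to total",
        c["septic_encounters"], float(t.table3["sepsis"].sum()), 0))
    checks.append(AuditCheck(
        "pooled sepsis prevalence (%)",
        c["prevalence_pct"],
        ev.round_half_away(100.0 * c["septic_encounters"] / c["total_encounters"], 2),
        0))
    checks.append(AuditCheck(
        "target FPR (%) from 15 alerts/day at 208 encounters/day",
        c["target_fpr_pct"],
        ev.round_half_away(100.0 * c["fp_per_day_budget"] / c["encounters_per_day"], 1),
        0))

    # Binary-AUC identity for every alert row of the threshold table.
    for label, row in t.table2.iterrows():
        checks.append(AuditCheck(
            f"binary AUC identity, {label} row",
            row["auc"],
            ev.binary_auc(row["sens_pct"] / 100.0, row["fpr_pct"] / 100.0),
            0.001))

    # Alerts/day reconciliation: FPR (printed to 0.1%) x negatives / 456 days.
    for label, row in t.table2.iterrows():
        checks.append(AuditCheck(
            f"alerts/day from FPR, {label} row",
            row["fp_per_day"],
            ev.fp_per_day_from_rate(row["fpr_pct"] / 100.0,
                                    c["nonseptic_encounters"], c["study_days"]),
            0.3))

    # Monthly stability: CV rows recomputed from the printed monthly values.
    # FPR columns are printed to one decimal only, so their CVs carry the
    # rounding of their inputs; the others reproduce at print precision.
    cv_specs = [
        ("rate_pct", 2, 0.0), ("cont_auc", 3, 0.0),
        ("model_sens_pct", 1, 0.0), ("model_fpr_pct", 1, 0.3),
        ("model_fp_per_day", 2, 0.0), ("model_auc", 3, 0.0),
        ("nurse_sens_pct", 1, 0.0), ("nurse_fpr_pct", 1, 0.3),
        ("nurse_fp_per_day", 2, 0.0), ("nurse_auc", 3, 0.0),
    ]
    rates = t.table3["sepsis"] / t.table3["encounters"]
    for col, nd, tol in cv_specs:
        vals = 100.0 * rates if col == "rate_pct" else t.table3[col]
        cv = ev.coefficient_of_variation(vals)
        if col.endswith("_pct"):
            cv *= 100.0
        checks.append(AuditCheck(
            f"monthly CV, {col}", t.table3_summary["cv"][col],
            ev.round_half_away(cv, nd), tol))

    # Min/max summary rows (exact on the printed monthlies; the rate column
    # is rounded to print precision before aggregating, as in the source).
    for agg in ("min", "max"):
        for col, target in t.table3_summary[agg].items():
            if col == "rate_pct":
                vals = [ev.round_half_away(r, 2) for r in 100.0 * rates]
            else:
                vals = t.table3[col]
            computed = float(getattr(np, agg)(vals))
            checks.append(AuditCheck(f"monthly {agg}, {col}", target, computed, 1e-9))

    # Pooled sensitivity rebuilt from monthly true-positive counts.
    checks.append(AuditCheck(
        "overall sensitivity (%) from monthly true positives",
        float(t.table2.loc["cut05", "sens_pct"]),
        ev.round_half_away(reconstruct_overall_sensitivity(t), 1),
        0))
    return checks
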