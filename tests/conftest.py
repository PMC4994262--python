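"""Shared fixtures: study tables and reusable synthetic cohorts.

Cohorts that take seconds to generate are session-scoped.  Calibration
checks use a balanced class mix (equal septic / non-septic counts via a
single exact-count stratum) so that per-class sampling error is negligible;
the study prevalence of 0.38 % is exercised by the calendar-replay and
end-to-end tests where exact label counts are the contract.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sepsiswatch import (
    CohortConfig,
    MonthStratum,
    default_cohort_config,
    load_printed_tables,
    simulate_cohort,
    table1_features,
)

#: Fixed seed for session cohorts: the study start date as an integer.
SESSION_SEED = 20090401


@pytest.fixture(scope="session")
def printed():
    return load_printed_tables()


@pytest.fixture(scope="session")
def balanced_config():
    """Study-calibrated marginals, 50/50 class mix, 100k encounters."""
    return CohortConfig(
        features=table1_features(),
        months=(MonthStratum("pooled", 100_000, 50_000),),
        seed=SESSION_SEED,
    )


@pytest.fixture(scope="session")
def balanced_cohort(balanced_config):
    return simulate_cohort(balanced_config)


@pytest.fixture(scope="session")
def calendar_cohort():
    """Replay of the study's 15-month calendar (93,773 encounters, 352 septic)."""
    return simulate_cohort(default_cohort_config(calendar=True, seed=SESSION_SEED))


@pytest.fixture()
def toy_scores():
    """Five scores with known ROC: septic {0.9, 0.7, 0.2}, non-septic {0.5, 0.1}."""
    scores = np.array([0.9, 0.7, 0.2, 0.5, 0.1])
    labels = np.array([1, 1, 1, 0, 0])
    return scores, labels


@pytest.fixture()
def tiny_labeled_frame():
    """Four encounters, one feature, hand-checkable naive Bayes fit."""
    df = pd.DataFrame({"x": [100.0, 120.0, 80.0, 90.0]})
    labels = np.array([1, 1, 0, 0])
    return df, labels
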