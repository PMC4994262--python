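"""Forward stepwise feature selection by bootstrap out-of-bag AUC.

The selection procedure mirrors how the deployed model was developed:
starting from the empty feature set, each remaining candidate is evaluated
by adding it to the current set, fitting the naive Bayes classifier on
bootstrap resamples, scoring the out-of-bag encounters of each resample,
and averaging the resulting AUCs.  The best candidate is accepted while its
mean out-of-bag AUC improves on the current model by at least a minimum
gain.  Clinician preference enters as a rank order that breaks ties among
candidates of statistically equivalent utility (mean OOB AUCs within an
equivalence band).

Because the outcome is rare (~0.4 %), the bootstrap is stratified by class
by default so every in-bag sample contains septic encounters.  Within one
selection step, all candidates are evaluated on the *same* bootstrap index
sets (common random numbers), which removes resampling noise from the
between-candidate comparison.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import auc_continuous
from .naive_bayes import fit, score_cohort

__all__ = ["SelectionConfig", "SelectionStep", "SelectionTrace",
           "oob_auc", "forward_select"]

_MAX_REDRAWS = 10


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the forward stepwise search.

    ``improvement_tol`` is the minimum mean-OOB-AUC gain required to accept
    another feature; ``equivalence_band`` is the AUC width within which
    ``preference_order`` (earlier = more preferred) overrides a small AUC
    advantage.
    """

    candidates: tuple[str, ...]
    n_bootstrap: int = 200
    improvement_tol: float = 0.002
    preference_order: tuple[str, ...] | None = None
    equivalence_band: float = 0.005
    stratified: bool = True
    max_features: int | None = None
    seed: int = 0
    sd_floor: float = 1e-6

    def __post_init__(self):
        object.__setattr__(self, "candidates", tuple(self.candidates))
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be at least 2")
        if self.improvement_tol < 0 or self.equivalence_band < 0:
            raise ValueError("tolerances must be non-negative")
        if self.preference_order is not None:
            object.__setattr__(self, "preference_order", tuple(self.preference_order))
            unknown = set(self.preference_order) - set(self.candidates)
            if unknown:
                raise ValueError(f"preference names not among candidates: {sorted(unknown)}")


@dataclass(frozen=True)
class SelectionStep:
    """Audit record of one accepted forward step."""

    feature: str
    mean_oob_auc: float
    candidate_aucs: dict[str, float]


@dataclass(frozen=True)
class SelectionTrace:
    """Accepted steps, final feature set, and why the search stopped."""

    steps: tuple[SelectionStep, ...]
    final_features: tuple[str, ...]
    stopped_reason: str  # "tolerance" | "max_features" | "exhausted"

    def to_dict(self) -> dict:
        return {
            "steps": [dataclasses.asdict(s) for s in self.steps],
            "final_features": list(self.final_features),
            "stopped_reason": self.stopped_reason,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _draw_bootstrap(rng: np.random.Generator, y: np.ndarray,
                    stratified: bool) -> np.ndarray:
    """In-bag row indices for one replicate (with replacement)."""
    n = y.size
    if stratified:
        parts = []
        for mask in (y, ~y):
            idx = np.flatnonzero(mask)
            parts.append(rng.choice(idx, size=idx.size, replace=True))
        return np.concatenate(parts)
    return rng.integers(0, n, size=n)


def _replicate_auc(X: np.ndarray, y: np.ndarray, in_bag: np.ndarray,
                   feat_idx: np.ndarray, sd_floor: float) -> float | None:
    """OOB AUC of one bootstrap replicate, or None if the replicate is invalid.

    Invalid: the out-of-bag rows lack a class, or some feature has fewer
    than two observed in-bag values in either class.
    """
    oob = np.ones(y.size, dtype=bool)
    oob[in_bag] = False
    y_oob = y[oob]
    if not (y_oob.any() and (~y_oob).any()):
        return None
    yb = y[in_bag]
    if not (yb.any() and (~yb).any()):
        return None
    Xb = X[np.ix_(in_bag, feat_idx)]
    llr = np.zeros(int(oob.sum()), dtype=float)
    X_oob = X[np.ix_(oob, feat_idx)]
    prior_logit = np.log(yb.mean()) - np.log1p(-yb.mean())
    for j in range(feat_idx.size):
        col = Xb[:, j]
        params = []
        for mask in (yb, ~yb):
            vals = col[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size < 2:
                return None
            params.append((vals.mean(), max(vals.std(ddof=1), sd_floor)))
        (m1, s1), (m0, s0) = params
        x = X_oob[:, j]
        obs = ~np.isnan(x)
        if obs.any():
            xo = x[obs]
            llr[obs] += (-0.5 * ((xo - m1) / s1) ** 2 - np.log(s1)
                         + 0.5 * ((xo - m0) / s0) ** 2 + np.log(s0))
    return auc_continuous(prior_logit + llr, y_oob)


def _oob_aucs_for_sets(X: np.ndarray, y: np.ndarray,
                       feature_sets: Sequence[np.ndarray],
                       n_bootstrap: int, stratified: bool,
                       rng: np.random.Generator,
                       sd_floor: float) -> np.ndarray:
    """Per-replicate OOB AUCs for several feature sets on shared bootstraps.

    Returns an array of shape (len(feature_sets), n_bootstrap).  A replicate
    is redrawn (bounded retries) until it is valid for *every* feature set,
    keeping the comparison paired.
    """
    out = np.empty((len(feature_sets), n_bootstrap), dtype=float)
    for b in range(n_bootstrap):
        for attempt in range(_MAX_REDRAWS + 1):
            in_bag = _draw_bootstrap(rng, y, stratified)
            aucs = [_replicate_auc(X, y, in_bag, fs, sd_floor) for fs in feature_sets]
            if all(a is not None for a in aucs):
                out[:, b] = aucs
                break
        else:
            raise RuntimeError(
                f"could not form a valid bootstrap replicate after {_MAX_REDRAWS} retries")
    return out


def _prepare(encounters: pd.DataFrame, labels, names: Sequence[str]):
    y = np.asarray(labels).astype(bool)
    if len(y) != len(encounters):
        raise ValueError("labels and encounters must have equal length")
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    X = encounters[list(names)].to_numpy(dtype=float)
    return X, y


def oob_auc(encounters: pd.DataFrame, labels, feature_set: Sequence[str],
            n_bootstrap: int = 200, stratified: bool = True, seed: int = 0,
            sd_floor: float = 1e-6) -> tuple[float, np.ndarray]:
    """Mean and per-replicate bootstrap out-of-bag AUCs for one feature set.

    Each replicate draws a bootstrap sample (stratified by class when
    configured), fits the naive Bayes model on the in-bag rows, scores the
    out-of-bag rows, and computes the concordance AUC.  Replicates whose
    out-of-bag set lacks a class (or whose in-bag data cannot be fitted)
    are redrawn up to a bounded number of times.
    """
    X, y = _prepare(encounters, labels, feature_set)
    rng = np.random.default_rng(seed)
    idx = np.arange(X.shape[1])
    aucs = _oob_aucs_for_sets(X, y, [idx], n_bootstrap, stratified, rng, sd_floor)[0]
    return float(aucs.mean()), aucs


def forward_select(encounters: pd.DataFrame, labels,
                   config: SelectionConfig) -> SelectionTrace:
    """Greedy forward search maximizing mean bootstrap out-of-bag AUC.

    The empty model's baseline AUC is 0.5.  At each step every remaining
    candidate is scored (on shared bootstrap draws); the top candidate is
    accepted if its gain reaches ``improvement_tol``, with the preference
    order breaking ties inside the equivalence band.  Deterministic given
    ``config.seed``.
    """
    X, y = _prepare(encounters, labels, config.candidates)
    col = {name: i for i, name in enumerate(config.candidates)}
    pref_rank = ({name: r for r, name in enumerate(config.preference_order)}
                 if config.preference_order else {})
    rng = np.random.default_rng(config.seed)

    selected: list[str] = []
    steps: list[SelectionStep] = []
    current_auc = 0.5
    stopped_reason = "exhausted"

    while True:
        remaining = [c for c in config.candidates if c not in selected]
        if not remaining:
            stopped_reason = "exhausted"
            break
        if config.max_features is not None and len(selected) >= config.max_features:
            stopped_reason = "max_features"
            break
        sets = [np.array([col[f] for f in selected + [cand]], dtype=int)
                for cand in remaining]
        auc_matrix = _oob_aucs_for_sets(X, y, sets, config.n_bootstrap,
                                        config.stratified, rng, config.sd_floor)
        cand_aucs = dict(zip(remaining, auc_matrix.mean(axis=1)))
        best_auc = max(cand_aucs.values())
        eligible = [c for c in remaining
                    if cand_aucs[c] >= best_auc - config.equivalence_band]
        # Preferred candidate wins inside the equivalence band; otherwise the
        # highest AUC (first in candidate order on exact ties).
        chosen = min(eligible,
                     key=lambda c: (pref_rank.get(c, len(config.candidates)),
                                    -cand_aucs[c]))
        if cand_aucs[chosen] - current_auc < config.improvement_tol:
            stopped_reason = "tolerance"
            break
        selected.append(chosen)
        current_auc = float(cand_aucs[chosen])
        steps.append(SelectionStep(
            feature=chosen,
            mean_oob_auc=current_auc,
            candidate_aucs={k: float(v) for k, v in cand_aucs.items()},
        ))
    return SelectionTrace(steps=tuple(steps), final_features=tuple(selected),
                          stopped_reason=stopped_reason)
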