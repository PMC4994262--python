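"""Gaussian naive Bayes sepsis classifier with native missing-data handling.

The classifier mirrors the structure used by bedside Bayesian alerting
systems: a class prior (sepsis prevalence) and, for every feature, a
Gaussian likelihood per class parameterized by the mean and standard
deviation observed among septic and non-septic patients.  The posterior for
an encounter multiplies the class prior by the likelihood of each *observed*
feature; a missing feature simply contributes nothing to either class, so
no imputation is ever performed.  This makes the model robust to the heavy,
informative missingness of first-hour ED laboratory values (a lactate is
drawn on a third of septic patients but almost no non-septic ones), at the
cost of discarding the information carried by the fact of measurement
itself.

All posterior arithmetic happens in log space; the public surface returns
probabilities.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["FeatureModel", "NaiveBayesModel", "fit", "score_cohort"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FeatureModel:
    """Per-class Gaussian parameters for one feature, in feature units."""

    name: str
    mean_septic: float
    sd_septic: float
    mean_nonseptic: float
    sd_nonseptic: float

    def __post_init__(self):
        if self.sd_septic <= 0 or self.sd_nonseptic <= 0:
            raise ValueError(f"feature {self.name!r}: standard deviations must be positive")


@dataclass(frozen=True)
class NaiveBayesModel:
    """Class prior plus per-feature, per-class Gaussian likelihoods.

    Parameters
    ----------
    prior
        Probability of sepsis before any feature is observed, in (0, 1).
        By default :func:`fit` estimates it from training prevalence.
    features
        One :class:`FeatureModel` per modeled feature; names unique.
    sd_floor
        Lower bound applied to fitted standard deviations so a constant
        column cannot produce a degenerate (zero-width) density.
    """

    prior: float
    features: tuple[FeatureModel, ...] = field(default_factory=tuple)
    sd_floor: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie strictly in (0, 1)")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    # -- scoring -----------------------------------------------------------

    def log_likelihood_ratio(self, encounters: pd.DataFrame) -> np.ndarray:
        """Sum over observed features of log N(x; septic) - log N(x; non-septic).

        Missing entries (NaN) contribute exactly zero to both classes.
        """
        missing = [f.name for f in self.features if f.name not in encounters.columns]
        if missing:
            raise KeyError(f"model features absent from table: {missing}")
        llr = np.zeros(len(encounters), dtype=float)
        for f in self.features:
            x = encounters[f.name].to_numpy(dtype=float)
            obs = ~np.isnan(x)
            if not obs.any():
                continue
            xo = x[obs]
            llr[obs] += _gauss_logpdf(xo, f.mean_septic, f.sd_septic)
            llr[obs] -= _gauss_logpdf(xo, f.mean_nonseptic, f.sd_nonseptic)
        return llr

    def score(self, encounters: pd.DataFrame) -> np.ndarray:
        """Posterior sepsis probability for every row; order preserved."""
        logit_prior = math.log(self.prior) - math.log1p(-self.prior)
        return expit(logit_prior + self.log_likelihood_ratio(encounters))

    def posterior(self, encounter: Mapping) -> float:
        """Posterior sepsis probability for a single encounter.

        ``encounter`` is any mapping (dict, pandas Series) from feature name
        to value; a feature that is absent, None, or NaN is skipped, so an
        all-missing encounter returns the prior exactly.
        """
        row = {}
        for f in self.features:
            v = encounter.get(f.name) if hasattr(encounter, "get") else None
            row[f.name] = float("nan") if v is None else float(v)
        return float(self.score(pd.DataFrame([row]))[0])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prior": self.prior,
            "sd_floor": self.sd_floor,
            "features": [dataclasses.asdict(f) for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NaiveBayesModel":
        return cls(
            prior=d["prior"],
            sd_floor=d.get("sd_floor", 1e-6),
            features=tuple(FeatureModel(**f) for f in d["features"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NaiveBayesModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _gauss_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def fit(encounters: pd.DataFrame, labels, feature_names: Sequence[str],
        sd_floor: float = 1e-6, prior: float | None = None) -> NaiveBayesModel:
    """Estimate a :class:`NaiveBayesModel` from a labeled cohort.

    Per feature and class, the mean and SD (n-1 denominator) are computed
    over the *non-missing* values of that class only; rows missing the
    feature contribute nothing to its parameters.  The prior defaults to
    the training prevalence and can be overridden explicitly.

    Raises
    ------
    ValueError
        If a class is absent, or a requested feature has fewer than two
        observed values in either class (reported by name).
    """
    y = np.asarray(labels).astype(bool)
    if len(y) != len(encounters):
        raise ValueError("labels and encounters must have equal length")
    n_septic = int(y.sum())
    if n_septic == 0 or n_septic == y.size:
        raise ValueError("both septic and non-septic encounters are required (class absent)")

    features = []
    underpowered = []
    for name in feature_names:
        if name not in encounters.columns:
            raise KeyError(f"feature column {name!r} not in table")
        x = encounters[name].to_numpy(dtype=float)
        params = {}
        for cls_name, mask in (("septic", y), ("nonseptic", ~y)):
            vals = x[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size < 2:
                underpowered.append(f"{name} ({cls_name}: {vals.size} observed)")
                params = None
                break
            params[cls_name] = (float(vals.mean()), max(float(vals.std(ddof=1)), sd_floor))
        if params is not None:
            features.append(FeatureModel(
                name=name,
                mean_septic=params["septic"][0], sd_septic=params["septic"][1],
                mean_nonseptic=params["nonseptic"][0], sd_nonseptic=params["nonseptic"][1],
            ))
    if underpowered:
        raise ValueError(
            "features with fewer than 2 observed values in a class: "
            + "; ".join(underpowered)
        )
    return NaiveBayesModel(
        prior=n_septic / y.size if prior is None else prior,
        features=tuple(features),
        sd_floor=sd_floor,
    )


def score_cohort(model: NaiveBayesModel, encounters: pd.DataFrame) -> np.ndarray:
    """Vectorized posterior for every encounter (row order preserved)."""
    return model.score(encounters)
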