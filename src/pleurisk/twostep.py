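"""The gated two-step mesothelioma classifier.

Step 1 applies per-marker threshold *gates* chosen at full training
specificity: a hyaluronan concentration above ``cutoff_ha`` (reference
value 120 ug UA/mL) or an N-ERC/mesothelin concentration above
``cutoff_nerc`` (reference 1050 ng/mL) classifies the effusion as
mesothelioma outright.  Gating removes exactly the samples that would
otherwise cause quasi-complete separation in a joint regression.

Step 2 fits an ordinary logistic regression of outcome on
(log10 HA, log10 N-ERC) over the remaining, sub-gate samples.  A sample
below both gates is called positive when its predicted risk exceeds
``risk_threshold``.

The printed form of the risk equation in the source literature is
internally inconsistent; the model implemented here is the standard
logistic risk

    risk = expit(b0 + b_ha * log10(HA) + b_nerc * log10(NERC)),

the unique sign convention under which the reference coefficient set
(b0 = -12.42, b_ha = 4.71, b_nerc = 2.71) together with the 120/1050
gates and the 0.9 risk threshold behaves sensibly (benign profiles get
near-zero risk, gate-adjacent profiles high risk).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, Sample, log_transform
from .errors import DegenerateDataError, SeparationError
from .univariate import fit_logistic

__all__ = [
    "TwoStepClassifier",
    "Prediction",
    "fit_full_specificity_cutoff",
    "fit_two_step",
    "predict_risk",
    "classify_cohort",
    "reference_model",
    "save_model",
    "load_model",
]

#: Routes a prediction can take.
ROUTE_GATE_HA = "gate_ha"
ROUTE_GATE_NERC = "gate_nerc"
ROUTE_LOGISTIC = "logistic"


def fit_full_specificity_cutoff(values, y) -> float:
    """Gate cut-off at full training specificity.

    Returns the maximum marker value among non-events, so that the rule
    ``value > cutoff -> positive`` misclassifies no training non-event.
    """
    values = np.asarray(values, float)
    y = np.asarray(y, int)
    neg = values[y == 0]
    if neg.size == 0:
        raise DegenerateDataError("no non-events: full-specificity cut-off undefined")
    return float(neg.max())


class TwoStepClassifier(BaseEstimator, ClassifierMixin):
    """Gated two-step classifier over (hyaluronan, N-ERC/mesothelin).

    Parameters
    ----------
    cutoff_ha, cutoff_nerc
        Gate cut-offs on the raw concentration scale.  ``None`` (default)
        fits them at full training specificity (maximum over training
        non-events); a number freezes the gate, e.g. at the reference
        values 120 and 1050.
    risk_threshold
        Predicted-risk operating point for the logistic step, in (0, 1).
        Default 0.9; 0.81 is the external-validation operating point.

    Attributes
    ----------
    cutoff_ha_, cutoff_nerc_ : float
        Gates actually applied.
    intercept_ : float
        Logistic intercept b0.
    coef_ : ndarray of shape (2,)
        Slopes (b_ha, b_nerc) per unit log10 concentration.
    cov_params_ : ndarray of shape (3, 3)
        Inverse observed information of (b0, b_ha, b_nerc).
    n_gated_, n_modelled_ : int
        Training samples removed by the gates / kept for the regression.
    """

    _feature_names = ("ha", "nerc")

    def __init__(
        self,
        cutoff_ha: float | None = None,
        cutoff_nerc: float | None = None,
        risk_threshold: float = 0.9,
    ):
        self.cutoff_ha = cutoff_ha
        self.cutoff_nerc = cutoff_nerc
        self.risk_threshold = risk_threshold

    # -- fitting -------------------------------------------------------
    def fit(self, X, y, cohort_name: str | None = None) -> "TwoStepClassifier":
        """Fit gates and sub-gate logistic regression.

        ``X`` is (n, 2): raw HA and N-ERC concentrations (columns in that
        order; a DataFrame with 'ha'/'nerc' columns is reordered).
        """
        X, y = self._validate(X, y=y)
        if not 0.0 < self.risk_threshold < 1.0:
            raise ValueError("risk_threshold must lie in (0, 1)")
        for c, label in ((self.cutoff_ha, "cutoff_ha"), (self.cutoff_nerc, "cutoff_nerc")):
            if c is not None and c <= 0:
                raise ValueError(f"{label} must be > 0")
        ha, nerc = X[:, 0], X[:, 1]

        self.cutoff_ha_ = (
            float(self.cutoff_ha)
            if self.cutoff_ha is not None
            else fit_full_specificity_cutoff(ha, y)
        )
        self.cutoff_nerc_ = (
            float(self.cutoff_nerc)
            if self.cutoff_nerc is not None
            else fit_full_specificity_cutoff(nerc, y)
        )

        sub = (ha <= self.cutoff_ha_) & (nerc <= self.cutoff_nerc_)
        y_sub = y[sub]
        if y_sub.size == 0 or y_sub.min() == y_sub.max():
            raise DegenerateDataError(
                "sub-gate subset lacks events or non-events; consider overriding "
                "cutoff_ha/cutoff_nerc"
            )
        logs = np.column_stack([log_transform(ha[sub]), log_transform(nerc[sub])])
        try:
            fit = fit_logistic(logs, y_sub, names=self._feature_names)
        except SeparationError as exc:
            raise SeparationError(
                f"separation below the gates — the gates failed their purpose: {exc}",
                predictors=exc.predictors,
            ) from exc
        self.intercept_ = fit.intercept
        self.coef_ = fit.slopes
        self.cov_params_ = fit.covariance
        self.n_modelled_ = int(sub.sum())
        self.n_gated_ = int(len(y) - sub.sum())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        self.cohort_name_ = cohort_name
        return self

    # -- prediction ------------------------------------------------------
    def risk(self, X) -> np.ndarray:
        """Predicted mesothelioma risk per sample (gate routes score 1.0)."""
        check_is_fitted(self, "intercept_")
        X = self._validate(X)
        ha, nerc = X[:, 0], X[:, 1]
        eta = (
            self.intercept_
            + self.coef_[0] * log_transform(ha)
            + self.coef_[1] * log_transform(nerc)
        )
        risk = expit(eta)
        gate = (ha > self.cutoff_ha_) | (nerc > self.cutoff_nerc_)
        risk[gate] = 1.0
        return risk

    def routes(self, X) -> np.ndarray:
        """Decision route per sample: gate_ha, gate_nerc or logistic.

        The HA gate is checked first; a sample above both gates is labelled
        gate_ha (the outcome is route-order independent, the label is not).
        """
        check_is_fitted(self, "intercept_")
        X = self._validate(X)
        out = np.full(len(X), ROUTE_LOGISTIC, dtype=object)
        out[X[:, 1] > self.cutoff_nerc_] = ROUTE_GATE_NERC
        out[X[:, 0] > self.cutoff_ha_] = ROUTE_GATE_HA
        return out.astype(str)

    def predict_proba(self, X) -> np.ndarray:
        r = self.risk(X)
        return np.column_stack([1.0 - r, r])

    def predict(self, X) -> np.ndarray:
        r = self.risk(X)
        gate = self.routes(X) != ROUTE_LOGISTIC
        return (gate | (r > self.risk_threshold)).astype(int)

    # -- plumbing --------------------------------------------------------
    def _validate(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            cols = [c for c in self._feature_names if c in X.columns]
            if len(cols) == 2:
                X = X[list(self._feature_names)]
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns (ha, nerc)")
        if not np.isfinite(X).all():
            raise ValueError("concentrations must be finite (drop missing markers first)")
        if (X < 0).any():
            raise ValueError("concentrations must be non-negative")
        if y is None:
            return X
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (mesothelioma = 1)")
        if y.min() == y.max():
            raise DegenerateDataError("need both outcome classes to fit")
        return X, y

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = True
        return tags


# ---------------------------------------------------------------------------
# Cohort-level wrappers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    """Per-patient model output."""

    patient_id: str
    risk: float
    route: str
    positive: bool


def fit_two_step(
    cohort: Cohort,
    risk_threshold: float = 0.9,
    cutoff_ha: float | None = None,
    cutoff_nerc: float | None = None,
) -> TwoStepClassifier:
    """Fit a :class:`TwoStepClassifier` on a cohort's HA/N-ERC columns.

    Samples lacking either marker are dropped (their count is recorded in
    ``n_dropped_``).
    """
    frame = cohort.marker_frame(["ha", "nerc"])
    model = TwoStepClassifier(
        cutoff_ha=cutoff_ha, cutoff_nerc=cutoff_nerc, risk_threshold=risk_threshold
    )
    model.fit(
        frame[["ha", "nerc"]].to_numpy(),
        frame["outcome"].to_numpy(),
        cohort_name=cohort.name,
    )
    model.n_dropped_ = len(cohort) - len(frame)
    return model


def predict_risk(model: TwoStepClassifier, sample: Sample) -> Prediction:
    """Predict one sample; rejects samples missing a required marker."""
    for marker in ("ha", "nerc"):
        if marker not in sample.markers:
            raise KeyError(f"sample {sample.patient_id!r} lacks marker {marker!r}")
    X = np.array([[sample.markers["ha"], sample.markers["nerc"]]])
    risk = float(model.risk(X)[0])
    route = str(model.routes(X)[0])
    positive = bool(model.predict(X)[0])
    return Prediction(sample.patient_id, risk, route, positive)


def classify_cohort(
    model: TwoStepClassifier, cohort: Cohort
) -> tuple[pd.DataFrame, dict]:
    """Apply a fitted model to a whole cohort.

    Returns per-sample predictions and a summary with the confusion counts,
    sensitivity/specificity at the model's operating point, the number of
    positives attributed to each route, and the count of samples dropped
    for missing markers.
    """
    frame = cohort.marker_frame(["ha", "nerc"])
    X = frame[["ha", "nerc"]].to_numpy()
    y = frame["outcome"].to_numpy()
    risk = model.risk(X)
    route = model.routes(X)
    positive = model.predict(X).astype(bool)

    predictions = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "outcome": y,
            "risk": risk,
            "route": route,
            "positive": positive,
        }
    )
    tp = int(np.sum(positive & (y == 1)))
    fn = int(np.sum(~positive & (y == 1)))
    fp = int(np.sum(positive & (y == 0)))
    tn = int(np.sum(~positive & (y == 0)))
    route_counts = {
        r: int(np.sum(positive & (route == r)))
        for r in (ROUTE_GATE_HA, ROUTE_GATE_NERC, ROUTE_LOGISTIC)
    }
    summary = {
        "n": int(len(y)),
        "n_dropped": int(len(cohort) - len(frame)),
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "positives_by_route": route_counts,
    }
    return predictions, summary


# ---------------------------------------------------------------------------
# Reference coefficient set and serialization
# ---------------------------------------------------------------------------

def reference_model(risk_threshold: float = 0.9) -> TwoStepClassifier:
    """The reference two-step model for pleural effusions.

    Gates at 120 ug UA/mL (hyaluronan) and 1050 ng/mL (N-ERC/mesothelin);
    logistic coefficients b0 = -12.42, b_ha = 4.71, b_nerc = 2.71 per unit
    log10 concentration; default operating point risk > 0.9.
    """
    model = TwoStepClassifier(cutoff_ha=120.0, cutoff_nerc=1050.0, risk_threshold=risk_threshold)
    model.cutoff_ha_ = 120.0
    model.cutoff_nerc_ = 1050.0
    model.intercept_ = -12.42
    model.coef_ = np.array([4.71, 2.71])
    model.cov_params_ = np.full((3, 3), np.nan)
    model.n_gated_ = 0
    model.n_modelled_ = 0
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = 2
    model.cohort_name_ = "reference"
    return model


def save_model(model: TwoStepClassifier, path: str | Path) -> None:
    """Serialize a fitted model as a flat, human-readable key-value file."""
    check_is_fitted(model, "intercept_")
    doc = {
        "cutoff_ha": float(model.cutoff_ha_),
        "cutoff_nerc": float(model.cutoff_nerc_),
        "b0": float(model.intercept_),
        "b_ha": float(model.coef_[0]),
        "b_nerc": float(model.coef_[1]),
        "risk_threshold": float(model.risk_threshold),
        "cohort_name": model.cohort_name_,
        "n_gated": int(model.n_gated_),
        "n_modelled": int(model.n_modelled_),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model(path: str | Path) -> TwoStepClassifier:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = TwoStepClassifier(
        cutoff_ha=doc["cutoff_ha"],
        cutoff_nerc=doc["cutoff_nerc"],
        risk_threshold=doc["risk_threshold"],
    )
    model.cutoff_ha_ = float(doc["cutoff_ha"])
    model.cutoff_nerc_ = float(doc["cutoff_nerc"])
    model.intercept_ = float(doc["b0"])
    model.coef_ = np.array([doc["b_ha"], doc["b_nerc"]], float)
    model.cov_params_ = np.full((3, 3), np.nan)
    model.n_gated_ = int(doc.get("n_gated", 0))
    model.n_modelled_ = int(doc.get("n_modelled", 0))
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = 2
    model.cohort_name_ = doc.get("cohort_name")
    return model
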