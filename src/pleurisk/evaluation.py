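"""Discrimination, reclassification and calibration metrics.

These are the instruments used to compare the two-step model against the
single markers: empirical ROC curves with bootstrap AUC intervals,
sensitivity at a fixed specificity, net reclassification improvement
(categorical and continuous), integrated discrimination improvement
(defined as the difference of discrimination slopes), and calibration
summaries (risk-decile table, Spiegelhalter's z, Brier score,
Nagelkerke's R^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateDataError

__all__ = [
    "RocCurve",
    "ComparisonReport",
    "CalibrationReport",
    "roc_with_auc",
    "sensitivity_at_specificity",
    "nri",
    "idi",
    "discrimination_slope",
    "compare_models",
    "calibration",
]

logger = logging.getLogger(__name__)


def _check_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateDataError("both outcome classes required")


def _stratified_bootstrap_ci(stat, y, n_boot, seed, *arrays) -> tuple[float, float]:
    """Percentile CI of ``stat(y*, *arrays*)`` over outcome-stratified resamples."""
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    values = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, idx_pos.size, replace=True),
                rng.choice(idx_neg, idx_neg.size, replace=True),
            ]
        )
        values[b] = stat(y[take], *(a[take] for a in arrays))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    one_minus_specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivities,
                "one_minus_specificity": self.one_minus_specificities,
            }
        )


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic via midranks."""
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_with_auc(
    risks, y, n_boot_ci: int = 2000, seed: int | None = None
) -> RocCurve:
    """Empirical ROC curve with trapezoidal AUC and bootstrap percentile CI.

    The trapezoidal area over the empirical curve equals the tie-corrected
    Mann-Whitney statistic.  The CI uses an outcome-stratified bootstrap
    (``n_boot_ci`` resamples; 0 skips the CI).
    """
    risks = np.asarray(risks, float)
    y = np.asarray(y, int)
    _check_classes(y)
    fpr, tpr, thresholds = _sk_roc_curve(y, risks)
    auc = float(np.trapezoid(tpr, fpr))
    ci = None
    if n_boot_ci:
        ci = _stratified_bootstrap_ci(
            lambda yy, rr: _rank_auc(yy, rr), y, n_boot_ci, seed, risks
        )
    return RocCurve(
        thresholds=thresholds,
        sensitivities=tpr,
        one_minus_specificities=fpr,
        auc=auc,
        auc_ci=ci,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def sensitivity_at_specificity(risks, y, specificity_target: float) -> dict[str, float]:
    """Highest sensitivity among thresholds with specificity >= target.

    The classification rule is ``risk > threshold -> positive``.  Returns
    ``{"sensitivity": ..., "threshold": ...}``; when even the most
    conservative finite threshold cannot reach the target, sensitivity 0 at
    an infinite threshold is returned.
    """
    if not 0.0 < specificity_target <= 1.0:
        raise ValueError("specificity_target must lie in (0, 1]")
    risks = np.asarray(risks, float)
    y = np.asarray(y, int)
    _check_classes(y)
    pos, neg = risks[y == 1], risks[y == 0]
    distinct = np.unique(risks)
    candidates = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, distinct, [np.inf]])
    best = (0.0, np.inf)
    for t in np.unique(candidates):
        sp = float(np.mean(neg <= t))
        if sp < specificity_target:
            continue
        se = float(np.mean(pos > t))
        # prefer higher sensitivity; among equals, the lower threshold
        if se > best[0] or (se == best[0] and t < best[1]):
            best = (se, t)
    return {"sensitivity": best[0], "threshold": float(best[1])}


# ---------------------------------------------------------------------------
# Reclassification: NRI and IDI
# ---------------------------------------------------------------------------

def _nri_point(y, old, new, mode) -> float:
    events = y == 1
    if mode == "categorical":
        up = (~old.astype(bool)) & new.astype(bool)
        down = old.astype(bool) & (~new.astype(bool))
    else:
        up = new > old
        down = new < old
    p_up_e = up[events].mean()
    p_down_e = down[events].mean()
    p_up_ne = up[~events].mean()
    p_down_ne = down[~events].mean()
    return float((p_up_e - p_down_e) + (p_down_ne - p_up_ne))


def nri(
    old,
    new,
    y,
    mode: Literal["categorical", "continuous"] = "categorical",
    n_boot_ci: int = 0,
    seed: int | None = None,
) -> dict:
    """Net reclassification improvement between two models.

    categorical
        ``old``/``new`` are binary classifications; "up" means a move from
        negative to positive.
    continuous
        ``old``/``new`` are predicted risks; "up" means any increase.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)],
    so the value lies in [-2, 2].  CI by outcome-stratified bootstrap
    percentile when ``n_boot_ci > 0``.
    """
    old = np.asarray(old)
    new = np.asarray(new)
    y = np.asarray(y, int)
    _check_classes(y)
    if len(old) != len(new) or len(old) != len(y):
        raise ValueError("old, new and y must have equal length")
    if mode == "continuous":
        if old.dtype == bool or new.dtype == bool:
            raise ValueError("continuous NRI needs predicted risks, not binary calls")
        old = old.astype(float)
        new = new.astype(float)
    elif mode == "categorical":
        old = old.astype(bool)
        new = new.astype(bool)
    else:
        raise ValueError("mode must be 'categorical' or 'continuous'")

    value = _nri_point(y, old, new, mode)
    ci = None
    if n_boot_ci:
        ci = _stratified_bootstrap_ci(
            lambda yy, oo, nn: _nri_point(yy, oo, nn, mode), y, n_boot_ci, seed, old, new
        )
    return {"nri": value, "ci": ci, "mode": mode}


def discrimination_slope(risks, y) -> float:
    """Mean predicted risk in events minus mean predicted risk in non-events."""
    risks = np.asarray(risks, float)
    y = np.asarray(y, int)
    _check_classes(y)
    return float(risks[y == 1].mean() - risks[y == 0].mean())


def idi(old_risks, new_risks, y, n_boot_ci: int = 0, seed: int | None = None) -> dict:
    """Integrated discrimination improvement.

    Exactly the difference of discrimination slopes:
    ``idi = ds(new) - ds(old)``.  CI by outcome-stratified bootstrap.
    """
    old_risks = np.asarray(old_risks, float)
    new_risks = np.asarray(new_risks, float)
    y = np.asarray(y, int)
    _check_classes(y)
    ds_old = discrimination_slope(old_risks, y)
    ds_new = discrimination_slope(new_risks, y)
    value = ds_new - ds_old
    ci = None
    if n_boot_ci:
        ci = _stratified_bootstrap_ci(
            lambda yy, oo, nn: discrimination_slope(nn, yy) - discrimination_slope(oo, yy),
            y,
            n_boot_ci,
            seed,
            old_risks,
            new_risks,
        )
    return {"idi": value, "ci": ci, "ds_old": ds_old, "ds_new": ds_new}


@dataclass
class ComparisonReport:
    """Old-model vs new-model reclassification summary."""

    nri_categorical: float
    nri_categorical_ci: tuple[float, float] | None
    nri_continuous: float
    nri_continuous_ci: tuple[float, float] | None
    idi: float
    idi_ci: tuple[float, float] | None
    ds_old: float
    ds_new: float

    def to_dict(self) -> dict:
        return {
            "nri_categorical": self.nri_categorical,
            "nri_categorical_ci": list(self.nri_categorical_ci) if self.nri_categorical_ci else None,
            "nri_continuous": self.nri_continuous,
            "nri_continuous_ci": list(self.nri_continuous_ci) if self.nri_continuous_ci else None,
            "idi": self.idi,
            "idi_ci": list(self.idi_ci) if self.idi_ci else None,
            "ds_old": self.ds_old,
            "ds_new": self.ds_new,
        }


def compare_models(
    old_risks,
    new_risks,
    old_positive,
    new_positive,
    y,
    n_boot_ci: int = 2000,
    seed: int | None = None,
) -> ComparisonReport:
    """Full reclassification comparison of two risk models.

    Categorical NRI uses each model's binary calls at its own operating
    point; continuous NRI and IDI use the predicted risks.
    """
    cat = nri(old_positive, new_positive, y, "categorical", n_boot_ci, seed)
    cont = nri(old_risks, new_risks, y, "continuous", n_boot_ci, seed)
    delta = idi(old_risks, new_risks, y, n_boot_ci, seed)
    return ComparisonReport(
        nri_categorical=cat["nri"],
        nri_categorical_ci=cat["ci"],
        nri_continuous=cont["nri"],
        nri_continuous_ci=cont["ci"],
        idi=delta["idi"],
        idi_ci=delta["ci"],
        ds_old=delta["ds_old"],
        ds_new=delta["ds_new"],
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: Risks of exactly 0/1 (gate routes) are clipped by this amount inside the
#: likelihood-based calibration statistics only — never in classification.
_CLIP = 1e-9


@dataclass
class CalibrationReport:
    bins: pd.DataFrame            # mean_predicted, observed_fraction, n per bin
    spiegelhalter_z: float
    spiegelhalter_p: float
    brier: float
    nagelkerke_r2: float
    n_clipped: int

    def to_dict(self) -> dict:
        return {
            "spiegelhalter_z": self.spiegelhalter_z,
            "spiegelhalter_p": self.spiegelhalter_p,
            "brier": self.brier,
            "nagelkerke_r2": self.nagelkerke_r2,
            "n_clipped": self.n_clipped,
        }


def calibration(risks, y, n_bins: int = 10) -> CalibrationReport:
    """Calibration diagnostics for predicted risks.

    * risk-quantile bins (default deciles) with mean predicted risk,
      observed event fraction and bin size;
    * Spiegelhalter's z = sum((y-p)(1-2p)) / sqrt(sum((1-2p)^2 p (1-p)))
      with a two-sided normal p-value;
    * Brier score mean((p-y)^2) (computed on the unclipped risks);
    * Nagelkerke's R^2 from the Bernoulli likelihood of the supplied risks
      against the null (prevalence-only) model.

    Boundary risks (gate routes give exactly 1) are clipped inward by 1e-9
    for the likelihood-based statistics; the count of clipped values is
    reported.  All forecasts exactly 0.5 leave the z denominator at zero
    and are rejected as degenerate.
    """
    risks = np.asarray(risks, float)
    y = np.asarray(y, int)
    if ((risks < 0) | (risks > 1)).any():
        raise ValueError("risks must lie in [0, 1]")

    outside = (risks < _CLIP) | (risks > 1 - _CLIP)
    n_clipped = int(outside.sum())
    if n_clipped:
        logger.info("clipped %d boundary risks for calibration statistics", n_clipped)
    p = np.clip(risks, _CLIP, 1 - _CLIP)

    # binning on the raw (unclipped) predictions
    order = pd.qcut(risks, q=n_bins, duplicates="drop")
    bins = (
        pd.DataFrame({"risk": risks, "y": y, "bin": order})
        .groupby("bin", observed=True)
        .agg(mean_predicted=("risk", "mean"), observed_fraction=("y", "mean"), n=("y", "size"))
        .reset_index(drop=True)
    )

    denom = np.sum((1 - 2 * p) ** 2 * p * (1 - p))
    if denom == 0:
        raise DegenerateDataError("Spiegelhalter z undefined: all forecasts equal 0.5")
    z = float(np.sum((y - p) * (1 - 2 * p)) / np.sqrt(denom))
    p_value = float(2 * stats.norm.sf(abs(z)))

    brier = float(np.mean((risks - y) ** 2))

    n = len(y)
    p_bar = y.mean()
    if p_bar in (0.0, 1.0):
        # a one-class sample has no null-model likelihood contrast
        nagelkerke = float("nan")
    else:
        ll_model = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        ll_null = float(n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar)))
        cox_snell = 1.0 - np.exp(2.0 / n * (ll_null - ll_model))
        max_cs = 1.0 - np.exp(2.0 / n * ll_null)
        nagelkerke = float(cox_snell / max_cs)

    return CalibrationReport(
        bins=bins,
        spiegelhalter_z=z,
        spiegelhalter_p=p_value,
        brier=brier,
        nagelkerke_r2=nagelkerke,
        n_clipped=n_clipped,
    )
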