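"""Per-marker association and operating-point statistics.

For each marker the association with mesothelioma is summarised the way
diagnostic-marker panels usually are: a univariate logistic regression on
the log10 concentration (interquartile odds ratio with Wald CI and a
one-tailed p-value), an optimal cut-point that simultaneously optimises
sensitivity and specificity (max-min criterion, Youden tie-break), and
the positive likelihood ratio at that cut-point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort, log_transform
from .errors import DegenerateDataError, SeparationError

__all__ = [
    "LogisticFit",
    "CutpointResult",
    "LikelihoodRatio",
    "UnivariateResult",
    "fit_logistic",
    "interquartile_or",
    "optimal_cutpoint",
    "positive_likelihood_ratio",
    "univariate_table",
]

logger = logging.getLogger(__name__)

#: |slope| on the log10 scale beyond which estimates are treated as diverging
#: (quasi-complete separation).
SLOPE_LIMIT = 50.0


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    intercept: float
    slopes: np.ndarray
    covariance: np.ndarray       # (k+1, k+1), intercept first
    log_likelihood: float
    log_likelihood_null: float
    n: int
    names: tuple[str, ...]

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.slopes])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * (1 + len(self.slopes))

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        eta = self.intercept + x @ self.slopes
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(x, y, names: Sequence[str] | None = None) -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    Estimation is Newton-type IRLS with covariance equal to the inverse
    observed information.  Degenerate designs (a constant predictor) and
    complete/quasi-complete separation (perfect prediction, or a fitted
    |slope| above :data:`SLOPE_LIMIT`) are rejected with errors naming the
    offending predictor — separation is exactly the failure mode the
    two-step gates are designed to avoid.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.ndim(y) == 1 and len(y) == x.shape[1]:
        x = x.T
    y = np.asarray(y, float)
    if not np.isfinite(x).all():
        raise ValueError("predictors must be finite")
    if y.min() == y.max():
        raise DegenerateDataError("outcome has a single class; need events and non-events")
    k = x.shape[1]
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(k))
    for j in range(k):
        if np.ptp(x[:, j]) == 0:
            raise DegenerateDataError(f"predictor {names[j]!r} is constant")

    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        culprits = _separating_predictors(x, y, names)
        raise SeparationError(
            f"perfect separation in logistic fit (predictors {culprits or names})",
            predictors=culprits or names,
        ) from exc
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular information matrix: {exc}") from exc

    slopes = np.asarray(res.params[1:], float)
    big = np.abs(slopes) > SLOPE_LIMIT
    if big.any() and not res.mle_retvals.get("converged", True):
        # a huge slope alone can be a legitimate (steep but finite) MLE;
        # combined with non-convergence it means the estimates are diverging
        culprits = tuple(names[j] for j in np.flatnonzero(big))
        raise SeparationError(
            f"quasi-complete separation: |slope| > {SLOPE_LIMIT} and no "
            f"convergence for {culprits}",
            predictors=culprits,
        )
    return LogisticFit(
        intercept=float(res.params[0]),
        slopes=slopes,
        covariance=np.asarray(res.cov_params(), float),
        log_likelihood=float(res.llf),
        log_likelihood_null=float(res.llnull),
        n=int(len(y)),
        names=names,
    )


def _separating_predictors(x, y, names) -> tuple[str, ...]:
    """Single predictors whose class ranges do not overlap."""
    out = []
    pos, neg = x[y == 1], x[y == 0]
    for j, name in enumerate(names):
        if pos[:, j].min() >= neg[:, j].max() or neg[:, j].min() >= pos[:, j].max():
            out.append(name)
    return tuple(out)


def interquartile_or(
    beta: float, se: float, log_values: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Odds ratio for an interquartile-range increase of the log10 predictor.

    ``or_iqr = exp(beta * (Q3 - Q1))`` with quartiles taken over the whole
    modelling cohort (linear interpolation between order statistics); the
    95% CI exponentiates the Wald interval of beta scaled by the same IQR.
    """
    log_values = np.asarray(log_values, float)
    if log_values.size < 4:
        raise DegenerateDataError("need >= 4 values to form quartiles")
    q1, q3 = np.percentile(log_values, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise DegenerateDataError("interquartile range is zero")
    or_iqr = float(np.exp(beta * iqr))
    lo = float(np.exp((beta - 1.96 * se) * iqr))
    hi = float(np.exp((beta + 1.96 * se) * iqr))
    return or_iqr, (min(lo, hi), max(lo, hi))


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def optimal_cutpoint(scores, y) -> CutpointResult:
    """Threshold simultaneously optimising sensitivity and specificity.

    All candidate thresholds (midpoints between consecutive distinct sorted
    values, plus +/- infinity) are enumerated under the rule
    ``score > threshold -> positive``; the winner maximises
    ``min(sensitivity, specificity)``, ties broken by higher Youden index
    (se + sp - 1), then by the lower threshold.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both outcome classes required for a cut-point")
    distinct = np.unique(scores)
    candidates = [-np.inf, np.inf]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    best = None
    for t in candidates:
        se = float(np.mean(pos > t))
        sp = float(np.mean(neg <= t))
        key = (min(se, sp), se + sp - 1.0, -t)
        if best is None or key > best[0]:
            best = (key, t, se, sp)
    _, t, se, sp = best
    return CutpointResult(float(t), se, sp, degenerate=min(se, sp) == 0.0)


@dataclass(frozen=True)
class LikelihoodRatio:
    lr: float                     # inf when specificity == 1 and sensitivity > 0
    ci: tuple[float, float] | None


def positive_likelihood_ratio(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> LikelihoodRatio:
    """LR+ = sensitivity / (1 - specificity) with the standard log-method CI.

    At specificity 1 the ratio is infinite (flagged, no CI); at
    sensitivity 0 the log CI is undefined and omitted.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("counts must be positive")
    if specificity == 1.0:
        return LikelihoodRatio(np.inf if sensitivity > 0 else np.nan, None)
    lr = sensitivity / (1.0 - specificity)
    if sensitivity == 0.0:
        return LikelihoodRatio(0.0, None)
    se_log = np.sqrt(
        (1.0 - sensitivity) / (sensitivity * n_pos)
        + specificity / ((1.0 - specificity) * n_neg)
    )
    lo = float(np.exp(np.log(lr) - 1.96 * se_log))
    hi = float(np.exp(np.log(lr) + 1.96 * se_log))
    return LikelihoodRatio(float(lr), (lo, hi))


@dataclass(frozen=True)
class UnivariateResult:
    """One row of the per-marker association table."""

    marker: str
    beta: float                   # logistic slope per unit log10
    or_iqr: float
    or_ci: tuple[float, float]
    p_value: float                # one-tailed (direction: OR > 1)
    cutpoint: float               # on the raw concentration scale
    sensitivity: float
    specificity: float
    lr_positive: float
    lr_ci: tuple[float, float] | None
    n_used: int


def _one_tailed_p(beta: float, se: float) -> float:
    """One-tailed Wald p for the hypothesis OR > 1.

    Half the two-tailed p when the estimate points in the hypothesised
    direction (beta > 0), else one minus that half.
    """
    if se == 0:
        return np.nan
    z = beta / se
    two_tailed = 2.0 * stats.norm.sf(abs(z))
    return two_tailed / 2.0 if beta > 0 else 1.0 - two_tailed / 2.0


def univariate_table(cohort: Cohort, markers: Sequence[str] | None = None) -> list[UnivariateResult]:
    """Per-marker association statistics, ordered by descending or_iqr.

    Samples lacking a marker are dropped for that marker only (per-marker N
    is reported).  Markers absent for every sample are omitted with a
    logged warning; separation or degeneracy in a marker's fit is re-raised
    tagged with the marker name.
    """
    markers = list(markers) if markers is not None else cohort.marker_names
    results: list[UnivariateResult] = []
    for marker in markers:
        frame = cohort.marker_frame([marker])
        if frame.empty:
            logger.warning("marker %r absent for all samples; omitted", marker)
            continue
        values = frame[marker].to_numpy()
        y = frame["outcome"].to_numpy()
        logx = log_transform(values)
        try:
            fit = fit_logistic(logx[:, None], y, names=(marker,))
        except (SeparationError, DegenerateDataError) as exc:
            raise type(exc)(f"marker {marker!r}: {exc}") from exc
        beta = float(fit.slopes[0])
        se = float(fit.standard_errors[1])
        or_iqr, or_ci = interquartile_or(beta, se, logx)
        cut = optimal_cutpoint(values, y)
        lr = positive_likelihood_ratio(
            cut.sensitivity, cut.specificity, int(y.sum()), int((1 - y).sum())
        )
        results.append(
            UnivariateResult(
                marker=marker,
                beta=beta,
                or_iqr=or_iqr,
                or_ci=or_ci,
                p_value=_one_tailed_p(beta, se),
                cutpoint=cut.cutpoint,
                sensitivity=cut.sensitivity,
                specificity=cut.specificity,
                lr_positive=lr.lr,
                lr_ci=lr.ci,
                n_used=fit.n,
            )
        )
    results.sort(key=lambda r: r.or_iqr, reverse=True)
    return results


def univariate_frame(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Tabular (CSV-ready) form of :func:`univariate_table` output."""
    return pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "or_iqr": [r.or_iqr for r in results],
            "or_ci_low": [r.or_ci[0] for r in results],
            "or_ci_high": [r.or_ci[1] for r in results],
            "p_one_tailed": [r.p_value for r in results],
            "cutpoint": [r.cutpoint for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "lr_positive": [r.lr_positive for r in results],
            "lr_ci_low": [r.lr_ci[0] if r.lr_ci else np.nan for r in results],
            "lr_ci_high": [r.lr_ci[1] if r.lr_ci else np.nan for r in results],
            "n_used": [r.n_used for r in results],
        }
    )
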