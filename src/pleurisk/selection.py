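"""Bootstrap stepwise forward selection of markers.

Forward AIC selection run inside patient-level bootstrap resamples:
markers that carry reproducible signal are selected in (nearly) every
resample, pure-noise markers only sporadically.  Resampling is stratified
by outcome so that no resample loses all mesothelioma cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, log_transform
from .errors import DegenerateDataError

__all__ = ["SelectionResult", "forward_select_aic", "bootstrap_selection"]

logger = logging.getLogger(__name__)

#: |linear predictor| cap inside the selection-context IRLS; e^35 dwarfs any
#: realistic odds and keeps the boundary log-likelihood numerically clean.
_ETA_CAP = 35.0


def _aic_ml(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> float:
    """AIC of an unpenalized ML logistic fit, tolerant of separation.

    Stepwise selection needs the achieved log-likelihood even when a
    candidate set separates the outcome: the fit then converges towards the
    boundary, the deviance towards 0, so AIC -> 2k and further additions
    cannot help.  Raising on separation here would paradoxically punish the
    strongest markers, so this mirrors the glm/stepAIC behaviour of the
    reference tooling.  Implemented as damped IRLS (step-halving on
    likelihood decrease, capped linear predictor) so the boundary value is
    reached monotonically and deterministically.
    """
    y = np.asarray(y, float)
    k = X.shape[1]
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(k + 1)

    def loglik(b):
        eta = np.clip(design @ b, -_ETA_CAP, _ETA_CAP)
        p = expit(eta)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))), eta, p

    ll, eta, p = loglik(beta)
    for _ in range(max_iter):
        w = p * (1.0 - p)
        # tiny ridge keeps the weighted normal equations solvable at the boundary
        xtw = design.T * w
        h = xtw @ design + 1e-12 * np.eye(k + 1)
        step = np.linalg.solve(h, design.T @ (y - p))
        new_ll, new_eta, new_p = loglik(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll, new_eta, new_p = loglik(beta + step)
        if new_ll < ll:
            break
        beta += step
        converged = abs(new_ll - ll) < tol
        ll, eta, p = new_ll, new_eta, new_p
        if converged:
            break
    return -2.0 * ll + 2.0 * (k + 1)


@dataclass
class SelectionResult:
    """Marker selection frequencies over bootstrap resamples."""

    frequencies: dict[str, float]
    n_boot: int
    seed: int
    per_iteration_choices: list[list[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.frequencies.items(), key=lambda kv: -kv[1]),
            columns=["marker", "frequency"],
        )


def forward_select_aic(X: pd.DataFrame, y) -> list[str]:
    """Stepwise forward selection by AIC on log-scale predictors.

    Starts from the intercept-only model and at each step adds the
    candidate giving the largest AIC decrease (AIC = -2 logL + 2 k,
    k counting the intercept); stops when no addition lowers AIC.
    Separated candidate fits are evaluated at their boundary likelihood
    rather than rejected (see :func:`_aic_ml`); constant candidates are
    skipped with a logged note.  Returns markers in order of entry.
    """
    y = np.asarray(y, int)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate markers")
    if y.min() == y.max():
        raise DegenerateDataError("both outcome classes required")

    current_aic = _aic_ml(np.empty((len(y), 0)), y)
    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        best = None
        for candidate in remaining:
            cols = selected + [candidate]
            Xc = X[cols].to_numpy()
            if np.ptp(Xc[:, -1]) == 0:
                logger.debug("candidate %r constant in this resample; skipped", candidate)
                continue
            aic = _aic_ml(Xc, y)
            if best is None or aic < best[1]:
                best = (candidate, aic)
        if best is None or best[1] >= current_aic:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        current_aic = best[1]
    return selected


def bootstrap_selection(
    cohort: Cohort,
    markers: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    keep_choices: bool = False,
) -> SelectionResult:
    """Forward-AIC selection over ``n_boot`` stratified bootstrap resamples.

    Samples missing any candidate marker are dropped up front (a common
    complete-case matrix keeps iterations comparable).  Resamples draw
    patients with replacement within each outcome class, preserving the
    event / non-event split.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    markers = list(markers) if markers is not None else cohort.marker_names
    frame = cohort.marker_frame(markers)
    n_dropped = len(cohort) - len(frame)
    if n_dropped:
        logger.info("dropped %d samples missing one of %s", n_dropped, markers)
    X = pd.DataFrame(
        {m: log_transform(frame[m].to_numpy()) for m in markers}
    )
    y = frame["outcome"].to_numpy()
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)

    rng = np.random.default_rng(seed)
    counts = {m: 0 for m in markers}
    choices: list[list[str]] = []
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=idx_pos.size, replace=True),
                rng.choice(idx_neg, size=idx_neg.size, replace=True),
            ]
        )
        chosen = forward_select_aic(X.iloc[take].reset_index(drop=True), y[take])
        for m in chosen:
            counts[m] += 1
        if keep_choices:
            choices.append(chosen)
    freqs = {m: counts[m] / n_boot for m in markers}
    return SelectionResult(freqs, n_boot, seed, choices)
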