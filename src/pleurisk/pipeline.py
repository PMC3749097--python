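"""End-to-end orchestration: univariate table -> bootstrap selection ->
two-step fit -> prediction, evaluation, model comparison and calibration,
with full provenance (config and seed echoed into every report bundle)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, log_transform, read_cohort
from .errors import PipelineError
from .evaluation import calibration, compare_models, roc_with_auc, sensitivity_at_specificity
from .selection import bootstrap_selection
from .twostep import TwoStepClassifier, classify_cohort, fit_two_step, save_model
from .univariate import fit_logistic, univariate_frame, univariate_table

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    The seed drives every stochastic step (bootstrap selection and all
    bootstrap confidence intervals); two runs with identical config produce
    byte-identical reports.
    """

    input: str
    out_dir: str
    validation: str | None = None
    seed: int = 0
    n_boot: int = 1000
    n_boot_ci: int = 2000
    risk_threshold: float = 0.9
    cutoff_ha: float | None = None
    cutoff_nerc: float | None = None
    markers: list[str] = field(default_factory=list)
    schema: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _single_marker_risks(cohort_frame: pd.DataFrame, marker: str, train_frame: pd.DataFrame):
    """Univariate logistic risks for one marker, trained on the training frame."""
    logx_train = log_transform(train_frame[marker].to_numpy())
    fit = fit_logistic(logx_train[:, None], train_frame["outcome"].to_numpy(), names=(marker,))
    logx = log_transform(cohort_frame[marker].to_numpy())
    return fit.predict(logx[:, None])


def _evaluate_on(
    model: TwoStepClassifier,
    cohort: Cohort,
    train_frame: pd.DataFrame,
    config: RunConfig,
    out: Path,
    tag: str,
    written: list[Path],
) -> None:
    frame = cohort.marker_frame(["ha", "nerc"])
    X = frame[["ha", "nerc"]].to_numpy()
    y = frame["outcome"].to_numpy()

    predictions, summary = classify_cohort(model, cohort)
    path = out / f"predictions_{tag}.csv"
    predictions.to_csv(path, index=False)
    written.append(path)

    risk = model.risk(X)
    roc = roc_with_auc(risk, y, n_boot_ci=config.n_boot_ci, seed=config.seed)
    path = out / f"roc_{tag}.csv"
    roc.to_frame().to_csv(path, index=False)
    written.append(path)

    cal = calibration(risk, y)
    path = out / f"calibration_{tag}.csv"
    cal.bins.to_csv(path, index=False)
    written.append(path)

    comparisons = {}
    for marker, cutoff in (("ha", model.cutoff_ha_), ("nerc", model.cutoff_nerc_)):
        marker_risk = _single_marker_risks(frame, marker, train_frame)
        marker_positive = frame[marker].to_numpy() > cutoff
        report = compare_models(
            old_risks=marker_risk,
            new_risks=risk,
            old_positive=marker_positive,
            new_positive=model.predict(X).astype(bool),
            y=y,
            n_boot_ci=config.n_boot_ci,
            seed=config.seed,
        )
        comparisons[f"two_step_vs_{marker}"] = report.to_dict()

    report_doc = {
        "cohort": cohort.name,
        "n": int(len(y)),
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci) if roc.auc_ci else None,
        "sensitivity_at_full_specificity": sensitivity_at_specificity(risk, y, 1.0),
        "classification_summary": summary,
        "calibration": cal.to_dict(),
        "comparisons": comparisons,
    }
    path = out / f"evaluation_{tag}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(report_doc), fh, sort_keys=True)
    written.append(path)


def _plain(obj):
    """Recursively convert numpy scalars for clean YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns the bundle of written files by key.

    Any stage failure aborts with a :class:`PipelineError` naming the stage,
    and all partial outputs written so far are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        schema = config.schema or None
        train = read_cohort(config.input, schema=schema, aliases=config.aliases or None)
        valid = (
            read_cohort(config.validation, schema=schema, aliases=config.aliases or None)
            if config.validation
            else None
        )
        markers = config.markers or train.marker_names

        stage = "univariate"
        uni = univariate_table(train, markers)
        path = out / "univariate.csv"
        univariate_frame(uni).to_csv(path, index=False)
        written.append(path)

        stage = "selection"
        sel = bootstrap_selection(train, markers, n_boot=config.n_boot, seed=config.seed)
        path = out / "selection.csv"
        sel.to_frame().to_csv(path, index=False)
        written.append(path)

        stage = "fit"
        model = fit_two_step(
            train,
            risk_threshold=config.risk_threshold,
            cutoff_ha=config.cutoff_ha,
            cutoff_nerc=config.cutoff_nerc,
        )
        path = out / "model.yaml"
        save_model(model, path)
        written.append(path)

        train_frame = train.marker_frame(["ha", "nerc"])
        stage = "evaluate-training"
        _evaluate_on(model, train, train_frame, config, out, "training", written)

        if valid is not None:
            stage = "evaluate-validation"
            _evaluate_on(model, valid, train_frame, config, out, "validation", written)

        stage = "report"
        path = out / "run_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(config.to_dict()), fh, sort_keys=True)
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {p.stem: p for p in written}
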