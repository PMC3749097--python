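"""Gate fitting, risk prediction, routes, serialization and sklearn plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.base import clone

from pleurisk import (
    Cohort,
    DegenerateDataError,
    Sample,
    Diagnosis,
    TwoStepClassifier,
    classify_cohort,
    fit_full_specificity_cutoff,
    fit_two_step,
    load_model,
    predict_risk,
    reference_model,
    save_model,
)


class TestFullSpecificityCutoff:
    def test_max_over_non_events(self):
        cut = fit_full_specificity_cutoff([5, 30, 80, 20, 150, 400], [0, 0, 0, 1, 1, 1])
        assert cut == 80.0
        events = np.array([20.0, 150.0, 400.0])
        assert np.mean(events > cut) == pytest.approx(2 / 3)

    def test_useless_gate_still_valid(self):
        cut = fit_full_specificity_cutoff([1, 2, 50, 60], [1, 1, 0, 0])
        assert cut == 60.0  # all events below: sensitivity 0, specificity 1

    def test_single_non_event_forced(self):
        assert fit_full_specificity_cutoff([10, 99], [0, 1]) == 10.0

    def test_no_non_events_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_full_specificity_cutoff([1, 2], [1, 1])


class TestReferenceModelRisks:
    def test_gate_dominates_regardless_of_other_marker(self):
        model = reference_model()
        X = np.array([[150.0, 1.0], [150.0, 1e6]])
        assert (model.risk(X) == 1.0).all()
        assert (model.routes(X) == "gate_ha").all()
        assert (model.predict(X) == 1).all()

    def test_boundary_values_take_logistic_route(self):
        model = reference_model()
        X = np.array([[120.0, 1050.0]])
        assert model.routes(X)[0] == "logistic"
        assert model.risk(X)[0] == pytest.approx(0.9961673800615368, abs=1e-9)
        assert model.predict(X)[0] == 1  # 0.996 > 0.9

    def test_low_marker_profile_negative(self):
        model = reference_model()
        X = np.array([[10.0, 100.0]])
        assert model.risk(X)[0] == pytest.approx(0.09195454993100434, abs=1e-9)
        assert model.predict(X)[0] == 0

    def test_monotone_in_each_marker_including_gate_jump(self):
        model = reference_model()
        ha_grid = np.linspace(1, 200, 300)
        risks = model.risk(np.column_stack([ha_grid, np.full(300, 500.0)]))
        assert (np.diff(risks) >= -1e-12).all()
        nerc_grid = np.linspace(10, 2000, 300)
        risks = model.risk(np.column_stack([np.full(300, 50.0), nerc_grid]))
        assert (np.diff(risks) >= -1e-12).all()

    def test_gate_routes_order_independent_in_outcome(self):
        model = reference_model()
        X = np.array([[500.0, 5000.0]])  # above both gates
        assert model.predict(X)[0] == 1
        assert model.routes(X)[0] == "gate_ha"  # documented HA-first labelling


class TestFitTwoStep:
    def test_fitted_gates_exceed_every_training_negative(self, generation_cohort):
        model = fit_two_step(generation_cohort)
        frame = generation_cohort.marker_frame(["ha", "nerc"])
        neg = frame[frame["outcome"] == 0]
        assert (neg["ha"] <= model.cutoff_ha_).all()
        assert (neg["nerc"] <= model.cutoff_nerc_).all()
        # each gate alone has training specificity exactly 1
        assert (neg["ha"] > model.cutoff_ha_).sum() == 0
        assert (neg["nerc"] > model.cutoff_nerc_).sum() == 0

    def test_degenerate_subset_rejected(self):
        # all events above the HA gate -> sub-gate subset has no events
        frame = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(8)],
                "diagnosis": ["mesothelioma"] * 4 + ["benign"] * 4,
                "ha": [500, 600, 700, 800, 10, 20, 30, 40],
                "nerc": [100, 100, 100, 100, 90, 90, 90, 90],
            }
        )
        with pytest.raises(DegenerateDataError, match="overriding"):
            fit_two_step(Cohort("deg", frame))

    def test_parameter_recovery_on_sub_gate_simulation(self, rng):
        n = 2000
        b0, b_ha, b_nerc = -12.42, 4.71, 2.71
        log_ha = rng.uniform(0.5, np.log10(120), n)
        log_nerc = rng.uniform(1.5, np.log10(1050), n)
        y = rng.binomial(1, expit(b0 + b_ha * log_ha + b_nerc * log_nerc))
        frame = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "diagnosis": np.where(y == 1, "mesothelioma", "benign"),
                "ha": 10.0**log_ha,
                "nerc": 10.0**log_nerc,
            }
        )
        model = fit_two_step(Cohort("sim", frame), cutoff_ha=120.0, cutoff_nerc=1050.0)
        se = np.sqrt(np.diag(model.cov_params_))
        assert abs(model.intercept_ - b0) < 3 * se[0]
        assert abs(model.coef_[0] - b_ha) < 3 * se[1]
        assert abs(model.coef_[1] - b_nerc) < 3 * se[2]


class TestPredictionWrappers:
    def test_predict_risk_requires_both_markers(self):
        model = reference_model()
        sample = Sample("x1", Diagnosis.BENIGN, {"ha": 5.0})
        with pytest.raises(KeyError, match="nerc"):
            predict_risk(model, sample)

    def test_predict_risk_prediction_fields(self):
        model = reference_model()
        sample = Sample("x2", Diagnosis.MESOTHELIOMA, {"ha": 150.0, "nerc": 20.0})
        pred = predict_risk(model, sample)
        assert pred.route == "gate_ha" and pred.risk == 1.0 and pred.positive

    def test_classify_cohort_routes_and_summary(self, generation_cohort):
        model = fit_two_step(generation_cohort)
        predictions, summary = classify_cohort(model, generation_cohort)
        assert len(predictions) == summary["n"] == len(generation_cohort)
        y = predictions["outcome"].to_numpy()
        pos = predictions["positive"].to_numpy()
        assert summary["tp"] == int((pos & (y == 1)).sum())
        assert summary["sensitivity"] == pytest.approx(summary["tp"] / y.sum())
        assert summary["specificity"] == pytest.approx(summary["tn"] / (len(y) - y.sum()))
        by_route = predictions[predictions["positive"]].groupby("route").size().to_dict()
        assert by_route == {k: v for k, v in summary["positives_by_route"].items() if v}
        # gate routes carry risk exactly 1
        gated = predictions[predictions["route"] != "logistic"]
        assert (gated["risk"] == 1.0).all()
        assert gated["positive"].all()

    def test_all_below_gates_all_logistic_routes(self):
        model = reference_model()
        X = np.array([[10.0, 100.0], [50.0, 900.0]])
        assert (model.routes(X) == "logistic").all()


class TestSerializationAndSklearnApi:
    def test_round_trip_bit_exact(self, tmp_path, generation_cohort):
        model = fit_two_step(generation_cohort)
        path = tmp_path / "model.yaml"
        save_model(model, path)
        back = load_model(path)
        assert back.cutoff_ha_ == model.cutoff_ha_
        assert back.cutoff_nerc_ == model.cutoff_nerc_
        assert back.intercept_ == model.intercept_
        assert (back.coef_ == model.coef_).all()
        assert back.risk_threshold == model.risk_threshold

    def test_get_set_params_and_clone(self):
        model = TwoStepClassifier(cutoff_ha=120, cutoff_nerc=1050, risk_threshold=0.81)
        params = model.get_params()
        assert params == {"cutoff_ha": 120, "cutoff_nerc": 1050, "risk_threshold": 0.81}
        twin = clone(model)
        assert twin.get_params() == params

    def test_predict_proba_columns_sum_to_one(self, generation_cohort):
        model = fit_two_step(generation_cohort)
        X = generation_cohort.marker_frame(["ha", "nerc"])[["ha", "nerc"]].to_numpy()
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (model.predict(X) == (proba[:, 1] > model.risk_threshold) | (model.routes(X) != "logistic")).all()

    def test_invalid_inputs_rejected(self):
        model = reference_model()
        with pytest.raises(ValueError):
            model.risk(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError):
            model.risk(np.array([[-1.0, 2.0]]))
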