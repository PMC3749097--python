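"""ROC/AUC, sensitivity at fixed specificity, NRI, IDI and calibration."""

import numpy as np
import pytest

from pleurisk import (
    DegenerateDataError,
    calibration,
    compare_models,
    discrimination_slope,
    idi,
    nri,
    roc_with_auc,
    sensitivity_at_specificity,
)


def brute_force_auc(risks, y):
    """Independent oracle: exhaustive pair counting with half-credit ties."""
    pos = risks[y == 1]
    neg = risks[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_with_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], n_boot_ci=0)
        assert roc.auc == 1.0

    def test_three_of_four_concordant(self):
        roc = roc_with_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], n_boot_ci=0)
        assert roc.auc == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            risks = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            roc = roc_with_auc(risks, y, n_boot_ci=0)
            assert roc.auc == pytest.approx(brute_force_auc(risks, y), abs=1e-12)

    def test_null_risks_auc_near_half(self, rng):
        y = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        risks = rng.uniform(0, 1, 4000)
        roc = roc_with_auc(risks, y, n_boot_ci=0)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_bootstrap_ci_brackets_auc(self, rng):
        y = rng.integers(0, 2, 200)
        y[:5] = 1
        y[-5:] = 0
        risks = rng.uniform(0, 1, 200) + 0.3 * y
        roc = roc_with_auc(risks, y, n_boot_ci=200, seed=1)
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_with_auc([0.1, 0.2], [1, 1], n_boot_ci=0)


class TestSensitivityAtSpecificity:
    def test_full_specificity_enumeration(self):
        res = sensitivity_at_specificity(
            [0.1, 0.2, 0.15, 0.3, 0.4], [0, 0, 1, 1, 1], 1.0
        )
        assert res["sensitivity"] == pytest.approx(2 / 3)
        assert res["threshold"] == pytest.approx(0.2)

    def test_unattainable_returns_zero(self):
        res = sensitivity_at_specificity([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 1.0)
        assert res["sensitivity"] == 0.0

    def test_matches_brute_force_at_half_specificity(self, rng):
        risks = rng.uniform(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[:3] = 1
        y[-3:] = 0
        res = sensitivity_at_specificity(risks, y, 0.5)
        pos, neg = risks[y == 1], risks[y == 0]
        best = 0.0
        for t in np.r_[-np.inf, np.sort(risks), np.inf]:
            if np.mean(neg <= t) >= 0.5:
                best = max(best, float(np.mean(pos > t)))
        assert res["sensitivity"] == pytest.approx(best)


class TestNri:
    def test_direct_counting_example(self):
        y = np.r_[np.ones(4, int), np.zeros(5, int)]
        old = np.array([0, 0, 1, 0, 0, 1, 1, 0, 0], bool)
        new = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0], bool)
        # events: 2 up, 1 down of 4; non-events: 1 up, 2 down of 5
        res = nri(old, new, y, "categorical")
        assert res["nri"] == pytest.approx((2 - 1) / 4 + (2 - 1) / 5)

    def test_identical_models_zero(self, rng):
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        calls = rng.integers(0, 2, 30).astype(bool)
        assert nri(calls, calls, y, "categorical")["nri"] == 0.0

    def test_perfect_vs_always_negative(self):
        y = np.array([1, 1, 0, 0])
        old = np.zeros(4, bool)
        new = y.astype(bool)
        assert nri(old, new, y, "categorical")["nri"] == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        old = rng.uniform(0, 1, 50)
        new = rng.uniform(0, 1, 50)
        forward = nri(old, new, y, "continuous")["nri"]
        backward = nri(new, old, y, "continuous")["nri"]
        assert forward == pytest.approx(-backward)

    def test_continuous_invariant_under_common_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        old = rng.uniform(0.01, 0.99, 50)
        new = rng.uniform(0.01, 0.99, 50)
        base = nri(old, new, y, "continuous")["nri"]
        warped = nri(np.log(old), np.log(new), y, "continuous")["nri"]
        assert warped == pytest.approx(base)

    def test_continuous_mode_rejects_binary_inputs(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="continuous"):
            nri(np.array([True, False, True, False]), np.array([False, True, False, True]), y, "continuous")


class TestIdi:
    def test_mean_arithmetic_example(self):
        y = np.array([1, 1, 0, 0])
        old = np.array([0.6, 0.6, 0.3, 0.3])
        new = np.array([0.8, 0.8, 0.2, 0.2])
        res = idi(old, new, y)
        assert res["ds_old"] == pytest.approx(0.3)
        assert res["ds_new"] == pytest.approx(0.6)
        assert res["idi"] == pytest.approx(0.3)

    def test_self_comparison_zero(self, rng):
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        p = rng.uniform(0, 1, 30)
        assert idi(p, p, y)["idi"] == 0.0

    def test_identity_with_discrimination_slopes_exact(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            y[0], y[1] = 0, 1
            old = rng.uniform(0, 1, 40)
            new = rng.uniform(0, 1, 40)
            res = idi(old, new, y)
            assert res["idi"] == discrimination_slope(new, y) - discrimination_slope(old, y)

    def test_antisymmetric_under_swap(self, rng):
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        old = rng.uniform(0, 1, 40)
        new = rng.uniform(0, 1, 40)
        assert idi(old, new, y)["idi"] == pytest.approx(-idi(new, old, y)["idi"])

    def test_compare_models_report_consistent(self, rng):
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        old = rng.uniform(0, 1, 60)
        new = np.clip(old + rng.normal(0.1, 0.1, 60), 0, 1)
        report = compare_models(old, new, old > 0.5, new > 0.5, y, n_boot_ci=100, seed=3)
        assert report.idi == pytest.approx(report.ds_new - report.ds_old)
        assert -2 <= report.nri_categorical <= 2
        assert -2 <= report.nri_continuous <= 2


class TestCalibration:
    def test_single_observation_hand_arithmetic(self):
        rep = calibration([0.2], [0], n_bins=1)
        assert rep.spiegelhalter_z == pytest.approx(-0.5)

    def test_perfect_forecasts_zero_brier(self):
        rep = calibration([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0], n_bins=2)
        assert rep.brier == 0.0
        assert rep.n_clipped == 4

    def test_null_model_nagelkerke_zero(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        rep = calibration(np.full(6, y.mean()), y, n_bins=2)
        assert rep.nagelkerke_r2 == pytest.approx(0.0, abs=1e-12)

    def test_all_half_forecasts_degenerate(self):
        with pytest.raises(DegenerateDataError):
            calibration([0.5, 0.5, 0.5], [0, 1, 0])

    def test_bin_sizes_sum_to_n(self, rng):
        p = rng.uniform(0.05, 0.95, 300)
        y = rng.binomial(1, p)
        rep = calibration(p, y)
        assert rep.bins["n"].sum() == 300

    def test_z_standard_normal_under_correct_calibration(self, rng):
        zs = []
        for _ in range(300):
            p = rng.uniform(0.05, 0.95, 300)
            y = rng.binomial(1, p)
            zs.append(calibration(p, y).spiegelhalter_z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.8 < zs.std(ddof=1) < 1.2

    def test_true_probabilities_beat_perturbed_on_brier(self, rng):
        wins = 0
        for _ in range(50):
            p = rng.uniform(0.1, 0.9, 400)
            y = rng.binomial(1, p)
            p_bad = np.clip(p + rng.normal(0, 0.15, 400), 0.01, 0.99)
            if calibration(p, y).brier <= calibration(p_bad, y).brier:
                wins += 1
        assert wins >= 40
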