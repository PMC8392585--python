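"""Discrimination, calibration, Hosmer-Lemeshow, classification, bootstrap
optimism correction and the frozen-model external validation path."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ntcpkit.model import reference_model
from ntcpkit.validation import (
    ValidationReport,
    auc_p_value,
    bootstrap_optimism,
    calibration,
    classification_at_cutoff,
    evaluate_predictions,
    external_validate,
    fit_only_recipe,
    hosmer_lemeshow,
    residual_analysis,
    risk_group_table,
    roc_auc,
)


def auc_pair_count_oracle(p, y):
    """Exhaustive concordant-pair counting (ties at 1/2)."""
    pos = [pi for pi, yi in zip(p, y) if yi == 1]
    neg = [pi for pi, yi in zip(p, y) if yi == 0]
    score = sum(
        1.0 if a > b else (0.5 if a == b else 0.0)
        for a, b in itertools.product(pos, neg)
    )
    return score / (len(pos) * len(neg))


def _simulated(rng, n, slope=1.0, offset=0.0):
    """Predictions and outcomes drawn from a shifted/rescaled logistic truth."""
    lp = rng.normal(0.0, 1.2, n)
    p = expit(lp)
    y = (rng.random(n) < expit(offset + slope * lp)).astype(int)
    return p, y


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            p = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(p, y) == pytest.approx(
                auc_pair_count_oracle(p, y), abs=1e-12
            )

    def test_independent_predictions_near_half(self, rng):
        p = rng.random(4000)
        y = rng.integers(0, 2, 4000)
        assert roc_auc(p, y) == pytest.approx(0.5, abs=0.03)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])

    def test_p_value_significant_only_for_signal(self, rng):
        p, y = _simulated(rng, 400)
        assert auc_p_value(p, y) < 1e-4
        y_null = rng.integers(0, 2, 400)
        assert auc_p_value(rng.random(400), y_null) > 0.01


class TestCalibration:
    def test_self_consistent_predictions(self, rng):
        p, y = _simulated(rng, 20000)
        cal = calibration(p, y)
        assert cal["slope"] == pytest.approx(1.0, abs=0.05)
        assert cal["in_the_large"] == pytest.approx(0.0, abs=0.05)

    def test_odds_shift_moves_citl_not_slope(self, rng):
        shift = np.log(3.0)
        p, y = _simulated(rng, 20000, offset=shift)
        cal = calibration(p, y)
        assert cal["in_the_large"] == pytest.approx(shift, abs=0.08)
        assert cal["slope"] == pytest.approx(1.0, abs=0.08)

    def test_overfitted_spread_gives_slope_below_one(self, rng):
        # predictions twice as extreme as the truth => slope about 0.5
        lp = rng.normal(0.0, 1.2, 20000)
        y = (rng.random(20000) < expit(lp)).astype(int)
        cal = calibration(expit(2.0 * lp), y)
        assert cal["slope"] == pytest.approx(0.5, abs=0.05)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            calibration([0.0, 0.5, 0.7], [0, 1, 1])
        with pytest.raises(ValueError):
            calibration([0.5, 0.5, 0.5], [0, 1, 1])


def hl_hand_oracle(p, y, bounds):
    """Sigma (O-E)^2/E over both cells with explicit group bounds."""
    chi2, pos = 0.0, 0
    for b in bounds:
        gp, gy = np.asarray(p[pos:b]), np.asarray(y[pos:b])
        e1, o1 = gp.sum(), gy.sum()
        e0, o0 = (1 - gp).sum(), len(gy) - gy.sum()
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        pos = b
    return chi2


class TestHosmerLemeshow:
    def test_matches_hand_built_oracle(self, rng):
        p = np.sort(rng.uniform(0.05, 0.95, 60))
        y = (rng.random(60) < p).astype(int)
        res = hosmer_lemeshow(p, y, groups=6)
        assert res["chi2"] == pytest.approx(
            hl_hand_oracle(p, y, [10, 20, 30, 40, 50, 60]), abs=1e-10
        )
        assert res["df"] == 4

    def test_remainder_goes_to_lowest_risk_groups(self, rng):
        p = np.sort(rng.uniform(0.05, 0.95, 62))  # 62 = 6*10 + 2
        y = (rng.random(62) < p).astype(int)
        res = hosmer_lemeshow(p, y, groups=6)
        assert res["chi2"] == pytest.approx(
            hl_hand_oracle(p, y, [11, 22, 32, 42, 52, 62]), abs=1e-10
        )

    def test_tied_predictions_stay_together(self):
        # one tie block of 8 identical values among 12: groups must not split it
        p = np.array([0.1, 0.1] + [0.5] * 8 + [0.9, 0.9])
        y = [0, 0, 0, 1, 0, 1, 0, 1, 0, 1, 1, 1]
        res = hosmer_lemeshow(p, y, groups=3)
        assert res["chi2"] == pytest.approx(hl_hand_oracle(p, y, [2, 10, 12]), abs=1e-10)

    def test_well_calibrated_large_sample_high_p(self, rng):
        p = rng.uniform(0.1, 0.9, 5000)
        y = (rng.random(5000) < p).astype(int)
        assert hosmer_lemeshow(p, y)["p"] > 0.01

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1], groups=2)


class TestClassification:
    def test_hand_counted_confusion(self):
        p = [0.9, 0.7, 0.6, 0.3, 0.8, 0.2]
        y = [1, 1, 0, 0, 0, 1]
        res = classification_at_cutoff(p, y, cutoff=0.65)
        assert (res["tp"], res["fp"], res["tn"], res["fn"]) == (2, 1, 2, 1)
        assert res["ppv"] == pytest.approx(2 / 3)
        assert res["npv"] == pytest.approx(2 / 3)

    def test_no_positive_calls_leaves_ppv_undefined(self):
        res = classification_at_cutoff([0.1, 0.2, 0.3], [0, 1, 0], cutoff=0.65)
        assert res["ppv"] is None
        assert res["npv"] == pytest.approx(2 / 3)


class TestResiduals:
    def test_flags_by_threshold_sign(self):
        p = [0.1, 0.9, 0.5, 0.25]
        y = [1, 0, 1, 0]
        res = residual_analysis(p, y, ids=["a", "b", "c", "d"], threshold=0.7)
        assert res["radiosensitive"] == ["a"]  # event despite p = 0.1
        assert res["radioresistant"] == ["b"]  # no event despite p = 0.9
        assert res["residuals"] == pytest.approx([0.9, -0.9, 0.5, -0.25])


class TestRiskGroups:
    def test_mean_predicted_tracks_observed_when_calibrated(self, rng):
        p = rng.uniform(0.05, 0.95, 3000)
        y = (rng.random(3000) < p).astype(int)
        rows = risk_group_table(p, y, groups=6)
        assert len(rows) == 6
        assert sum(r["n"] for r in rows) == 3000
        for r in rows:
            assert abs(r["observed_rate"] - r["mean_predicted"]) < 4 * r["se_observed"] + 0.02


class TestBootstrapOptimism:
    def _overfit_data(self, rng, n=100, k=10):
        X = pd.DataFrame(rng.standard_normal((n, k)),
                         columns=[f"x{i}" for i in range(k)])
        y = rng.integers(0, 2, n)
        return X, y

    def test_null_data_apparent_auc_optimistic(self, rng):
        X, y = self._overfit_data(rng)
        res = bootstrap_optimism(X, y, B=100, seed=3)
        assert res.apparent["auc"] > 0.55
        assert res.optimism["auc"] > 0.0
        assert res.corrected["auc"] < res.apparent["auc"]

    def test_b_zero_returns_apparent_uncorrected(self, rng):
        X, y = self._overfit_data(rng, n=60, k=3)
        res = bootstrap_optimism(X, y, B=0)
        assert res.corrected == res.apparent
        assert res.n_resamples == 0

    def test_deterministic_under_seed(self, rng):
        X, y = self._overfit_data(rng, n=80, k=4)
        r1 = bootstrap_optimism(X, y, B=40, seed=9)
        r2 = bootstrap_optimism(X, y, B=40, seed=9)
        assert r1.corrected == r2.corrected

    @pytest.mark.filterwarnings("ignore")  # pathological refits warn by design
    def test_rare_outcome_skip_limit(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        y = np.r_[np.ones(1, int), np.zeros(29, int)]
        with pytest.raises(RuntimeError, match="more than 10%"):
            bootstrap_optimism(X, y, B=200, seed=0)

    def test_custom_recipe_called(self, rng):
        X, y = self._overfit_data(rng, n=80, k=3)
        calls = []

        def recipe(Xb, yb):
            calls.append(1)
            return fit_only_recipe(Xb, yb)

        bootstrap_optimism(X, y, recipe=recipe, B=10, seed=0)
        assert len(calls) >= 11  # apparent fit + each accepted resample


class TestReports:
    def _cohort(self, rng, n=300):
        p, y = _simulated(rng, n)
        return p, y

    def test_report_assembly_and_invariants(self, rng):
        p, y = self._cohort(rng)
        rep = evaluate_predictions(p, y, cohort_label="dev")
        assert rep.n == 300
        assert rep.events == int(np.sum(y))
        assert 0 <= rep.auc <= 1
        assert rep.hl_chi2 >= 0
        assert rep.hl_groups == 6
        assert sum(rep.confusion.values()) == 300

    def test_json_round_trip(self, rng, tmp_path):
        p, y = self._cohort(rng)
        rep = evaluate_predictions(p, y, cohort_label="dev")
        rep.to_json(tmp_path / "r.json")
        back = ValidationReport.from_json(tmp_path / "r.json")
        assert back.auc == pytest.approx(rep.auc)
        assert back.cohort_label == "dev"
        assert back.risk_groups == rep.risk_groups

    def test_invalid_report_rejected(self):
        with pytest.raises(ValueError):
            ValidationReport(
                cohort_label="x", n=2, events=1, auc=1.2, auc_p=0.5,
                calibration_slope=1, calibration_in_the_large=0,
                mean_observed_minus_predicted=0, hl_chi2=1, hl_p=0.5,
                hl_groups=6, ppv=None, npv=None, cutoff=0.65,
                confusion={}, residual_flags={},
            )


class TestExternalValidate:
    def _cohort_frame(self, rng, n, odds_multiplier=1.0):
        m = reference_model()
        X = pd.DataFrame(
            {
                "cpg_d98": rng.normal(26.8, 9.5, n),
                "oc_eud": rng.normal(55.0, 6.0, n),
                "age_5y": rng.uniform(6, 16, n),
                "smoking": rng.integers(0, 2, n).astype(float),
            }
        )
        p_true = expit(logit(m.predict(X)) + np.log(odds_multiplier))
        y = (rng.random(n) < p_true).astype(int)
        return X, y

    def test_frozen_model_never_refit(self, rng):
        m = reference_model()
        X, y = self._cohort_frame(rng, 800)
        rep = external_validate(m, X, y, cohort_label="ext")
        p = m.predict(X)
        assert rep.auc == pytest.approx(roc_auc(p, y), abs=1e-12)
        assert rep.cohort_label == "ext"

    def test_self_consistent_cohort_calibrates(self, rng):
        X, y = self._cohort_frame(rng, 6000)
        rep = external_validate(reference_model(), X, y)
        assert rep.calibration_in_the_large == pytest.approx(0.0, abs=0.12)
        assert rep.calibration_slope == pytest.approx(1.0, abs=0.25)

    def test_odds_shifted_cohort_shows_citl(self, rng):
        X, y = self._cohort_frame(rng, 6000, odds_multiplier=3.0)
        rep = external_validate(reference_model(), X, y)
        assert rep.calibration_in_the_large == pytest.approx(np.log(3), abs=0.15)

    def test_missing_covariate_rejected(self, rng):
        X, y = self._cohort_frame(rng, 50)
        with pytest.raises(KeyError, match="smoking"):
            external_validate(reference_model(), X.drop(columns=["smoking"]), y)

    def test_model_loadable_from_json_path(self, rng, tmp_path):
        m = reference_model()
        m.to_json(tmp_path / "m.json")
        X, y = self._cohort_frame(rng, 400)
        rep_path = external_validate(tmp_path / "m.json", X, y)
        rep_obj = external_validate(m, X, y)
        assert rep_path.auc == pytest.approx(rep_obj.auc, abs=1e-12)

    def test_refit_effect_sizes_reported(self, rng):
        X, y = self._cohort_frame(rng, 600)
        rep = external_validate(
            reference_model(), X, y, refit_effect_sizes=True
        )
        assert rep.refit_odds_ratios is not None
        assert set(rep.refit_odds_ratios) <= {
            "cpg_d98", "oc_eud", "age_5y", "smoking"
        }
        for v in rep.refit_odds_ratios.values():
            assert v["CI_low"] < v["OR"] < v["CI_high"]
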