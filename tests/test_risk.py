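"""Horizon risks and threshold-based screening-interval allocation."""

import numpy as np
import pytest

from retscreen.impute import WorstCaseReference
from retscreen.markov import TransitionModel
from retscreen.risk import (
    allocate_interval,
    predict_cohort,
    predict_risk,
    predict_subject,
    predictions_to_frame,
)
from retscreen.simulate import SimulationConfig, simulate_cohort


class TestAllocateInterval:
    @pytest.mark.parametrize(
        "risks, threshold, expected",
        [
            ({0.5: 0.010, 1.0: 0.015, 2.0: 0.020}, 0.025, 2.0),
            ({0.5: 0.010, 1.0: 0.020, 2.0: 0.040}, 0.025, 1.0),
            ({0.5: 0.030, 1.0: 0.050, 2.0: 0.080}, 0.025, 0.5),
            ({0.5: 0.30, 1.0: 0.50, 2.0: 0.80}, 1.0, 2.0),
            ({0.5: 0.010, 1.0: 0.025, 2.0: 0.040}, 0.025, 1.0),  # tie is acceptable
        ],
        ids=["all_below", "middle", "floor", "degenerate_threshold", "tie_inclusive"],
    )
    def test_longest_acceptable_interval(self, risks, threshold, expected):
        assert allocate_interval(risks, threshold) == expected

    def test_decreasing_risks_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            allocate_interval({0.5: 0.05, 1.0: 0.02, 2.0: 0.06}, 0.025)


class TestPredictRisk:
    def test_one_year_risk_from_state_two_matches_reference_probability(self, true_model):
        # the calibrated baseline generator reproduces the reference
        # one-year 2->4 transition probability of 0.0163
        risks = predict_risk(true_model, 2, true_model.centering, horizons=(1.0,))
        assert risks[1.0] == pytest.approx(0.0163, abs=1e-6)

    def test_zero_horizon_gives_zero_risk(self, true_model):
        risks = predict_risk(true_model, 1, true_model.centering, horizons=(0.0, 1.0))
        assert risks[0.0] == 0.0

    def test_risks_monotone_and_interior(self, true_model):
        for state in (1, 2, 3):
            risks = predict_risk(true_model, state, true_model.centering)
            vals = [risks[h] for h in sorted(risks)]
            assert np.all(np.diff(vals) >= 0)
            assert all(0 < v < 1 for v in vals)

    def test_screen_positive_state_rejected(self, true_model):
        with pytest.raises(ValueError, match="already screen-positive"):
            predict_risk(true_model, 4, true_model.centering)


class TestPredictSubject:
    def test_worst_case_imputation_raises_risk(self):
        # covariates pushed risk-up on progression and risk-down on recovery,
        # so the 75th percentile is unambiguously worse than the median
        model = TransitionModel(
            intercepts=np.log([0.25, 1.2, 0.47, 0.014, 0.95, 0.08]),
            coefficients={"hba1c": np.array([0.02, -0.01, 0.02, 0.02, -0.01, 0.02])},
            alpha=0.9,
            centering={"hba1c": 58.0},
            worst_case={"hba1c": 70.0},
        )
        with_missing = predict_subject(model, "s", 2, {"hba1c": np.nan})
        at_median = predict_subject(model, "s", 2, {"hba1c": 58.0})
        assert with_missing.imputed == ("hba1c",)
        assert at_median.imputed == ()
        for h in with_missing.risks:
            assert with_missing.risks[h] >= at_median.risks[h]

    def test_missing_without_reference_rejected(self):
        model = TransitionModel(
            intercepts=np.log([0.25, 1.2, 0.47, 0.014, 0.95, 0.08]),
            coefficients={"hba1c": np.full(6, 0.01)},
            alpha=0.9,
            centering={"hba1c": 58.0},
        )
        with pytest.raises(ValueError, match="worst-case"):
            predict_subject(model, "s", 1, {"hba1c": np.nan})

    def test_pooling_averages_risks(self, true_model):
        bumped = TransitionModel(
            intercepts=true_model.intercepts + np.log(1.5),
            coefficients=true_model.coefficients,
            alpha=true_model.alpha,
            centering=true_model.centering,
        )
        lone = predict_subject(true_model, "s", 2, true_model.centering)
        other = predict_subject(bumped, "s", 2, true_model.centering)
        pooled = predict_subject([true_model, bumped], "s", 2, true_model.centering)
        for h in pooled.risks:
            assert pooled.risks[h] == pytest.approx(
                0.5 * (lone.risks[h] + other.risks[h]), rel=1e-12
            )


class TestPredictCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        panel, _ = simulate_cohort(SimulationConfig(n_subjects=200, seed=55))
        return panel

    def test_screen_positive_subjects_skipped_with_warning(self, true_model, cohort):
        n_positive = sum(
            1 for _, g in cohort.iter_subjects() if g["state"].iloc[-1] == 4
        )
        assert n_positive > 0
        with pytest.warns(UserWarning, match="skipped"):
            preds, n_skipped = predict_cohort(true_model, cohort)
        assert n_skipped == n_positive
        assert len(preds) == cohort.n_subjects - n_positive

    def test_identical_subjects_get_identical_predictions(self, true_model):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "time_years": [0.0, 1.0, 0.0, 1.0],
                "state": [1, 2, 1, 2],
                "hba1c": [60.0] * 4,
                "disease_duration": [8.0] * 4,
                "age_at_diagnosis": [50.0] * 4,
                "systolic_bp": [130.0] * 4,
                "total_cholesterol": [4.0] * 4,
            }
        )
        from retscreen.panel import PanelData

        preds, _ = predict_cohort(true_model, PanelData(frame))
        assert preds[0].risks == preds[1].risks
        assert preds[0].allocated_interval == preds[1].allocated_interval

    def test_lower_threshold_never_lengthens_interval(self, true_model, cohort):
        import warnings

        intervals = {}
        for thr in (0.05, 0.025, 0.01):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                preds, _ = predict_cohort(true_model, cohort, threshold=thr)
            intervals[thr] = {p.subject_id: p.allocated_interval for p in preds}
        for sid in intervals[0.05]:
            assert intervals[0.025][sid] <= intervals[0.05][sid]
            assert intervals[0.01][sid] <= intervals[0.025][sid]

    def test_prediction_frame_schema(self, true_model, cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds, _ = predict_cohort(true_model, cohort)
        frame = predictions_to_frame(preds)
        assert set(frame.columns) >= {
            "subject_id",
            "state",
            "risk_6m",
            "risk_12m",
            "risk_24m",
            "interval_months",
            "threshold",
            "imputed_flags",
        }
        assert frame["interval_months"].isin([6, 12, 24]).all()
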