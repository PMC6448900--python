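"""Policy accounting, rank metrics, cross-validation and bootstrap optimism."""

import numpy as np
import pandas as pd
import pytest

from retscreen.evaluate import (
    allocation_error_rates,
    bootstrap_optimism,
    concordance_index,
    episode_accounting,
    horizon_discrimination,
    kfold_validate,
    outcomes_from_panel,
)
from retscreen.simulate import SimulationConfig, simulate_cohort

from .oracles import brute_force_auc, brute_force_cindex


class TestEpisodeAccounting:
    def test_multiplier_arithmetic(self):
        s = episode_accounting({0.5: 100, 1.0: 50, 2.0: 850})
        assert s.episodes == {0.5: 400, 1.0: 100, 2.0: 850}
        assert s.total_episodes == 1350
        assert s.reference_episodes == 2000
        assert s.pct_difference == pytest.approx(-32.5)

    def test_empty_cohort_flagged(self):
        s = episode_accounting({0.5: 0, 1.0: 0, 2.0: 0})
        assert s.total_episodes == 0
        assert s.pct_difference == 0.0
        assert s.empty_cohort

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            episode_accounting({0.5: -1, 1.0: 0, 2.0: 0})


class TestAllocationErrorRates:
    def _outcomes(self):
        return pd.DataFrame(
            [
                {"subject_id": "pos_late", "event": True, "time": 1.5},
                {"subject_id": "pos_early", "event": True, "time": 0.4},
                {"subject_id": "neg_long", "event": False, "time": 2.5},
                {"subject_id": "neg_short", "event": False, "time": 1.0},
            ]
        )

    def test_risk_based_rules(self):
        alloc = {"pos_late": 2.0, "pos_early": 0.5, "neg_long": 1.0, "neg_short": 2.0}
        s = allocation_error_rates(self._outcomes(), alloc)
        # pos_late at 24m: event (1.5y) before the screen -> overestimated;
        # pos_early at 6m: event at 0.4 before 0.5 -> also overestimated
        assert s.positive_correct == 0.0
        assert s.positive_overestimated == 1.0
        # neg_long at 12m is underestimated; neg_short excluded (<2y follow-up)
        assert s.negative_correct == 0.0
        assert s.n_excluded == 1

    def test_correct_allocations(self):
        alloc = {"pos_late": 1.0, "pos_early": 0.5, "neg_long": 2.0}
        s = allocation_error_rates(self._outcomes(), alloc)
        assert s.positive_correct == 0.5  # event at 1.5 >= 1.0 screen
        assert s.negative_correct == 1.0

    def test_annual_policy_structure(self):
        # fixed 12-month interval: negatives can never be 'correct'
        outcomes = self._outcomes()
        alloc = {sid: 1.0 for sid in outcomes["subject_id"]}
        s = allocation_error_rates(outcomes, alloc)
        assert s.negative_correct == 0.0
        assert s.negative_underestimated == 1.0
        assert s.positive_correct == 0.5  # event at 1.5y is after the 12m screen


class TestConcordance:
    def test_perfect_ordering(self):
        scores = np.array([0.9, 0.5, 0.3, 0.1])
        event = np.array([True, True, False, False])
        time = np.array([0.5, 1.0, 2.0, 2.0])
        assert concordance_index(scores, event, time) == 1.0

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(17)
        n = 200
        time = rng.uniform(0.2, 3.0, n)
        event = rng.random(n) < 0.4
        scores = rng.permutation(n).astype(float)
        assert concordance_index(scores, event, time) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_on_toy_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = rng.integers(4, 9)
            scores = rng.integers(0, 4, n).astype(float)  # forces score ties
            event = rng.random(n) < 0.6
            time = rng.integers(1, 4, n).astype(float)
            if not event.any():
                event[0] = True
            ours = concordance_index(scores, event, time)
            assert ours == pytest.approx(brute_force_cindex(scores, event, time), abs=1e-12)

    def test_matches_lifelines_when_tie_free(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(29)
        n = 60
        scores = rng.normal(size=n)
        time = rng.uniform(0.1, 5.0, n)
        event = rng.random(n) < 0.5
        event[:2] = True
        ours = concordance_index(scores, event, time)
        # lifelines orders by survival time and *low* predicted risk
        theirs = ll_cindex(time, -scores, event)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0, 2.0]), np.array([False, False]), np.array([1.0, 2.0]))


class TestHorizonDiscrimination:
    def test_separable_scores(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        event = np.array([True, True, False, False])
        time = np.array([0.5, 0.8, 3.0, 3.0])
        m = horizon_discrimination(scores, event, time, horizon=1.0, threshold=0.5)
        assert m["auc"] == 1.0 and m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_matches_brute_force_auc(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = rng.integers(4, 9)
            scores = rng.integers(0, 5, n) / 5.0
            event = rng.random(n) < 0.6
            time = rng.uniform(0.1, 3.0, n)
            pos = event & (time <= 1.0)
            neg = time > 1.0
            if not pos.any() or not neg.any():
                continue
            m = horizon_discrimination(scores, event, time, horizon=1.0, threshold=0.3)
            keep = pos | neg
            assert m["auc"] == pytest.approx(
                brute_force_auc(scores[keep], pos[keep]), abs=1e-12
            )

    def test_zero_threshold_degenerate(self):
        scores = np.array([0.4, 0.6, 0.1, 0.2])
        event = np.array([True, True, False, False])
        time = np.array([0.5, 0.8, 3.0, 3.0])
        m = horizon_discrimination(scores, event, time, horizon=1.0, threshold=0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_empty_class_rejected(self):
        scores = np.array([0.4, 0.6])
        with pytest.raises(ValueError, match="empty"):
            horizon_discrimination(
                scores, np.array([False, False]), np.array([3.0, 3.0]), 1.0, 0.1
            )


class TestOutcomes:
    def test_midpoint_convention(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "a", "a", "b", "b"],
                "time_years": [0.0, 1.0, 2.0, 0.0, 1.5],
                "state": [1, 2, 4, 1, 1],
            }
        )
        from retscreen.panel import PanelData

        out = outcomes_from_panel(PanelData(frame)).set_index("subject_id")
        assert out.loc["a", "event"] and out.loc["a", "time"] == pytest.approx(1.5)
        assert not out.loc["b", "event"] and out.loc["b", "time"] == 1.5

    def test_exact_times_override_midpoint(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "time_years": [0.0, 2.0],
                "state": [1, 4],
            }
        )
        truth = pd.DataFrame(
            {"subject_id": ["a", "a"], "time": [0.0, 1.2], "state": [1, 4]}
        )
        from retscreen.panel import PanelData

        out = outcomes_from_panel(PanelData(frame, validate=False), use_exact_times=truth)
        assert out.loc[0, "time"] == pytest.approx(1.2)


class TestKfold:
    @pytest.fixture(scope="class")
    def cohort(self):
        panel, truth = simulate_cohort(SimulationConfig(n_subjects=800, seed=202))
        return panel, truth

    def test_fold_assignment_deterministic_and_balanced(self, cohort):
        panel, _ = cohort
        a = kfold_validate(
            panel, k=4, seed=9, covariates=("disease_duration",), fix_alpha=0.9,
            ci_bootstrap=50,
        )
        b = kfold_validate(
            panel, k=4, seed=9, covariates=("disease_duration",), fix_alpha=0.9,
            ci_bootstrap=50,
        )
        assert a.fold_assignments == b.fold_assignments
        counts = np.bincount(list(a.fold_assignments.values()))
        assert counts.max() - counts.min() <= len(counts)
        assert 0.0 <= a.cindex <= 1.0
        assert ((a.horizon_metrics["auc"] >= 0) & (a.horizon_metrics["auc"] <= 1)).all()

    def test_too_few_events_rejected(self):
        panel, _ = simulate_cohort(SimulationConfig(n_subjects=40, seed=5))
        with pytest.raises(ValueError, match="folds"):
            kfold_validate(panel, k=8, covariates=(), fix_alpha=0.9)


class TestBootstrapOptimism:
    def test_constant_metric_has_zero_optimism(self):
        panel, _ = simulate_cohort(SimulationConfig(n_subjects=40, seed=61, n_visits=3))
        optimism, n_failed = bootstrap_optimism(
            panel,
            metric=lambda fit, data: 0.42,
            B=50,
            seed=13,
            covariates=(),
            fix_alpha=1.0,
            compute_cov=False,
        )
        assert optimism == 0.0
        assert n_failed == 0

    def test_small_replicate_count_rejected(self, small_cohort):
        panel, _ = small_cohort
        with pytest.raises(ValueError, match="B >= 50"):
            bootstrap_optimism(panel, metric=lambda f, d: 0.0, B=10)
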