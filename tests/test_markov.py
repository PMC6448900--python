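"""Intensity matrices, Weibull transition probabilities and the panel likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm as scipy_expm

from retscreen.markov import (
    MissingCovariateError,
    TransitionModel,
    build_intensity_matrix,
    expm_batch,
    intensity_matrix_from_rates,
    panel_log_likelihood,
    state_occupancy,
    transition_probability,
)
from retscreen.panel import PanelData
from retscreen.simulate import SimulationConfig, simulate_cohort
from retscreen.states import TRANSITIONS

from .conftest import random_generator_rates
from .oracles import oracle_panel_loglik, uniformization_probability


def _toy_model(**kwargs):
    defaults = dict(
        intercepts=np.log([0.25, 1.2, 0.47, 0.014, 0.95, 0.08]),
        coefficients={"disease_duration": np.log([1.0280, 0.983, 1.0261, 0.989, 0.959, 1.0042])},
        alpha=0.9,
        centering={"disease_duration": 10.0},
    )
    defaults.update(kwargs)
    return TransitionModel(**defaults)


class TestIntensityMatrix:
    def test_baseline_covariates_give_intercept_intensities(self):
        model = _toy_model()
        Q = build_intensity_matrix(model, {"disease_duration": 10.0})
        for k, (i, j) in enumerate(TRANSITIONS):
            assert Q[i - 1, j - 1] == pytest.approx(np.exp(model.intercepts[k]), rel=1e-12)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        # forbidden entries of the generator
        assert Q[0, 2] == 0 and Q[0, 3] == 0 and Q[2, 0] == 0
        assert np.all(Q[3] == 0)

    def test_per_unit_hazard_ratio_scales_intensity(self):
        # one extra year of disease duration multiplies the 1->2 intensity
        # by its published per-unit hazard ratio 1.0280
        model = _toy_model()
        q0 = build_intensity_matrix(model, {"disease_duration": 10.0})[0, 1]
        q1 = build_intensity_matrix(model, {"disease_duration": 11.0})[0, 1]
        assert q1 / q0 == pytest.approx(1.0280, rel=1e-12)

    def test_ten_unit_shift_compounds_per_unit_ratio(self):
        model = _toy_model()
        q0 = build_intensity_matrix(model, {"disease_duration": 10.0})[0, 1]
        q10 = build_intensity_matrix(model, {"disease_duration": 20.0})[0, 1]
        compounded = 1.0
        for _ in range(10):
            compounded *= 1.0280
        assert q10 / q0 == pytest.approx(compounded, rel=1e-10)
        assert compounded == pytest.approx(1.31805, abs=5e-6)

    def test_missing_covariate_directs_to_imputation(self):
        with pytest.raises(MissingCovariateError, match="imputation"):
            build_intensity_matrix(_toy_model(), {"disease_duration": np.nan})


class TestExpmBatch:
    def test_matches_scipy_on_random_generators(self):
        rng = np.random.default_rng(5)
        A = intensity_matrix_from_rates(rng.uniform(0.01, 2.0, (40, 6)))
        A *= rng.uniform(0.01, 4.0, 40)[:, None, None]
        ours = expm_batch(A)
        ref = np.stack([scipy_expm(a) for a in A])
        assert np.abs(ours - ref).max() < 1e-12

    def test_overshoot_below_clip_tolerance(self):
        rng = np.random.default_rng(6)
        A = intensity_matrix_from_rates(rng.uniform(0.01, 2.0, (100, 6)))
        P = expm_batch(A)
        assert P.min() > -1e-12
        assert P.max() < 1 + 1e-12


class TestTransitionProbability:
    def test_zero_elapsed_time_is_identity(self):
        Q = intensity_matrix_from_rates(np.full(6, 0.5))
        P = transition_probability(Q, 1.3, 1.3, alpha=0.9)
        assert np.allclose(P, np.eye(4), atol=1e-14)

    def test_unit_time_ignores_alpha(self):
        Q = intensity_matrix_from_rates(np.array([0.3, 0.9, 0.4, 0.02, 0.8, 0.05]))
        for alpha in (0.5, 0.9, 1.0, 1.7):
            P = transition_probability(Q, 0.0, 1.0, alpha)
            assert np.allclose(P, scipy_expm(Q), atol=1e-12)

    def test_two_state_closed_form(self):
        # single escape route 1->2 at rate 1: P12 over [0,1] is 1 - e^-1
        Q = intensity_matrix_from_rates(np.array([1.0, 0, 0, 0, 0, 0]))
        P = transition_probability(Q, 0.0, 1.0, alpha=1.0)
        assert P[0, 1] == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert P[0, 1] == pytest.approx(0.63212, abs=5e-6)
        # and in operational time: 1 - exp(-(t2^a - t1^a))
        lam, a, t1, t2 = 0.7, 0.9, 0.5, 2.0
        Q = intensity_matrix_from_rates(np.array([lam, 0, 0, 0, 0, 0]))
        P = transition_probability(Q, t1, t2, alpha=a)
        assert P[0, 1] == pytest.approx(1 - np.exp(-lam * (t2**a - t1**a)), abs=1e-12)

    def test_rejects_reversed_interval(self):
        Q = intensity_matrix_from_rates(np.full(6, 0.1))
        with pytest.raises(ValueError):
            transition_probability(Q, 2.0, 1.0, alpha=0.9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), du=st.floats(0.0, 5.0))
    def test_rows_are_stochastic(self, seed, du):
        rng = np.random.default_rng(seed)
        Q = intensity_matrix_from_rates(random_generator_rates(rng))
        P = transition_probability(Q, 0.0, du, alpha=1.0) if du else np.eye(4)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0 and P.max() <= 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_semigroup_in_operational_time(self, seed):
        rng = np.random.default_rng(seed)
        Q = intensity_matrix_from_rates(random_generator_rates(rng))
        alpha = rng.uniform(0.5, 1.5)
        t1, t2 = sorted(rng.uniform(0.1, 4.0, 2))
        left = transition_probability(Q, 0, t1, alpha) @ transition_probability(Q, t1, t2, alpha)
        right = transition_probability(Q, 0, t2, alpha)
        assert np.abs(left - right).max() < 1e-8

    def test_absorption_probability_nondecreasing(self):
        rng = np.random.default_rng(11)
        Q = intensity_matrix_from_rates(random_generator_rates(rng))
        grid = np.linspace(0.0, 6.0, 40)
        for start in (1, 2, 3):
            p4 = [state_occupancy(Q, t, 0.9, start)[3] for t in grid]
            assert np.all(np.diff(p4) >= -1e-12)


class TestStateOccupancy:
    def test_time_zero_is_point_mass(self):
        Q = intensity_matrix_from_rates(np.full(6, 0.4))
        assert np.allclose(state_occupancy(Q, 0.0, 0.9, 2), [0, 1, 0, 0], atol=1e-14)

    def test_absorbing_start_stays_absorbed(self):
        Q = intensity_matrix_from_rates(np.full(6, 0.4))
        for t in (0.5, 2.0, 10.0):
            assert np.allclose(state_occupancy(Q, t, 0.9, 4), [0, 0, 0, 1], atol=1e-14)


class TestPanelLogLikelihood:
    def test_single_interval_is_log_entry(self, true_model):
        import pandas as pd

        frame = pd.DataFrame(
            {"subject_id": ["x", "x"], "time_years": [0.0, 1.0], "state": [1, 1]}
        )
        model = TransitionModel(intercepts=true_model.intercepts, alpha=0.9)
        ll = panel_log_likelihood(PanelData(frame), model)
        Q = intensity_matrix_from_rates(np.exp(model.intercepts))
        expected = np.log(transition_probability(Q, 0, 1, 0.9)[0, 0])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_additive_over_subjects(self, true_model):
        panel, _ = simulate_cohort(SimulationConfig(n_subjects=6, seed=3))
        ids = panel.subject_ids
        whole = panel_log_likelihood(panel, true_model)
        parts = sum(
            panel_log_likelihood(panel.subset([sid]), true_model) for sid in ids
        )
        assert whole == pytest.approx(parts, abs=1e-9)

    @pytest.mark.parametrize("alpha", [1.0, 0.9])
    def test_agrees_with_uniformization_oracle(self, alpha):
        # random small cohorts, intensities <= 2/yr, <= 3 intervals each
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            model = TransitionModel(
                intercepts=np.log(random_generator_rates(rng)),
                coefficients={
                    "hba1c": rng.normal(0, 0.01, 6),
                    "disease_duration": rng.normal(0, 0.02, 6),
                },
                alpha=alpha,
                centering={"hba1c": 58.0, "disease_duration": 10.0},
            )
            panel, _ = simulate_cohort(
                SimulationConfig(n_subjects=5, model=model, n_visits=4, seed=seed)
            )
            ours = panel_log_likelihood(panel, model)
            oracle = oracle_panel_loglik(panel, model)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_impossible_interval_returns_neg_inf_with_diagnostic(self, true_model):
        import pandas as pd

        # a departure from the absorbing state has probability exactly zero;
        # bypass validation to exercise the likelihood's diagnostic path
        frame = pd.DataFrame(
            {"subject_id": ["z", "z", "z"], "time_years": [0.0, 1.0, 2.0], "state": [1, 4, 1]}
        )
        panel = PanelData(frame, validate=False)
        model = TransitionModel(intercepts=true_model.intercepts, alpha=0.9)
        with pytest.warns(UserWarning, match="z"):
            ll = panel_log_likelihood(panel, model)
        assert ll == -np.inf
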