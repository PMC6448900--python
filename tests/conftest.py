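import numpy as np
import pandas as pd
import pytest

from retscreen.model import RetinopathyMarkovModel
from retscreen.panel import PanelData
from retscreen.simulate import SimulationConfig, default_true_model, simulate_cohort


@pytest.fixture(scope="session")
def true_model():
    return default_true_model()


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject complete synthetic cohort under the reference model."""
    panel, truth = simulate_cohort(SimulationConfig(n_subjects=300, seed=1234))
    return panel, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick two-covariate fit reused by summary/Wald/selection tests."""
    panel, _ = small_cohort
    model = RetinopathyMarkovModel(
        panel, covariates=("disease_duration", "hba1c"), fix_alpha=0.9
    )
    return model.fit()


@pytest.fixture()
def tiny_panel_frame():
    """Two subjects, four episodes, fully observed."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b"],
            "time_years": [0.0, 1.1, 0.0, 0.9],
            "state": [1, 2, 2, 4],
            "age_at_diagnosis": [50.0, 50.0, 61.0, 61.0],
            "disease_duration": [5.0, 5.0, 12.0, 12.0],
            "hba1c": [55.0, 55.0, 70.0, 70.0],
            "systolic_bp": [130.0, 130.0, 145.0, 145.0],
            "total_cholesterol": [4.5, 4.5, 5.5, 5.5],
        }
    )


@pytest.fixture()
def tiny_panel(tiny_panel_frame):
    return PanelData(tiny_panel_frame)


def random_generator_rates(rng: np.random.Generator, high: float = 2.0) -> np.ndarray:
    """Random intensities for the six permitted transitions."""
    return rng.uniform(0.01, high, 6)
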