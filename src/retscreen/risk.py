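"""Per-person screen-positive risk and screening-interval allocation.

The deployed behaviour of the engine: given a person's current retinopathy
state and clinical covariates, compute the probability of having become
screen-positive (state 4) by each candidate horizon — 6, 12 and 24 months —
and allocate the longest interval whose risk does not exceed the accepted
threshold (2.5% by default).  The clock restarts at the prediction episode:
risk at horizon h is the (state, 4) entry of expm(Q h^alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .impute import WorstCaseReference, missing_covariates, worst_case_impute
from .markov import TransitionModel, build_intensity_matrix, transition_probability
from .panel import PanelData
from .states import ABSORBING_STATE

#: Candidate screening intervals, in years (6, 12, 24 months).
DEFAULT_HORIZONS: tuple[float, ...] = (0.5, 1.0, 2.0)

#: Accepted risk of missing screen-positive disease within the interval.
DEFAULT_THRESHOLD = 0.025


@dataclass
class RiskPrediction:
    """One person's horizon risks and allocated screening interval."""

    subject_id: str
    state: int
    risks: dict[float, float]
    allocated_interval: float
    threshold: float
    imputed: tuple[str, ...] = field(default_factory=tuple)

    @property
    def interval_months(self) -> int:
        return int(round(self.allocated_interval * 12))


def predict_risk(
    model: TransitionModel,
    state: int,
    covariates: Mapping[str, float],
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> dict[float, float]:
    """Probability of reaching the screen-positive state by each horizon.

    Covariates must be complete — apply :func:`worst_case_impute` upstream
    for missing values.  Raises if the person is already screen-positive.
    """
    if state == ABSORBING_STATE:
        raise ValueError("subject is already screen-positive; no interval to allocate")
    if state not in (1, 2, 3):
        raise ValueError(f"state must be in 1..3, got {state}")
    Q = build_intensity_matrix(model, covariates)
    risks = {}
    for h in horizons:
        if h < 0:
            raise ValueError("horizons must be non-negative")
        P = transition_probability(Q, 0.0, h, model.alpha)
        risks[float(h)] = float(P[state - 1, ABSORBING_STATE - 1])
    return risks


def allocate_interval(risks: Mapping[float, float], threshold: float) -> float:
    """Longest horizon whose risk does not exceed the threshold.

    Risks must be non-decreasing in horizon; a risk exactly at the threshold
    counts as acceptable.  If even the shortest horizon exceeds the
    threshold, the shortest offered interval is returned.
    """
    horizons = sorted(risks)
    vals = [risks[h] for h in horizons]
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError(f"risks must be non-decreasing in horizon, got {vals}")
    allocated = horizons[0]
    for h in horizons:
        if risks[h] <= threshold:
            allocated = h
    return float(allocated)


def predict_subject(
    models: TransitionModel | Sequence[TransitionModel],
    subject_id: str,
    state: int,
    covariates: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    reference: WorstCaseReference | None = None,
) -> RiskPrediction:
    """Predict one person, pooling risks over several (imputation) models."""
    model_list = [models] if isinstance(models, TransitionModel) else list(models)
    needed = model_list[0].covariate_names
    imputed = tuple(c for c in missing_covariates(covariates, needed))
    if imputed:
        if reference is None:
            if not model_list[0].worst_case:
                raise ValueError(
                    "covariates are missing and the model carries no worst-case reference"
                )
            reference = WorstCaseReference.from_values(model_list[0].worst_case)
        covariates = worst_case_impute(covariates, reference)
    per_model = [predict_risk(m, state, covariates, horizons) for m in model_list]
    risks = {
        float(h): float(np.mean([r[float(h)] for r in per_model])) for h in horizons
    }
    return RiskPrediction(
        subject_id=str(subject_id),
        state=state,
        risks=risks,
        allocated_interval=allocate_interval(risks, threshold),
        threshold=threshold,
        imputed=imputed,
    )


def predict_cohort(
    models: TransitionModel | Sequence[TransitionModel],
    panel: PanelData,
    threshold: float = DEFAULT_THRESHOLD,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> tuple[list[RiskPrediction], int]:
    """One prediction per subject from their latest screen-negative episode.

    Subjects whose latest episode is already screen-positive are skipped;
    the second return value counts them.  Missing covariates are filled by
    worst-case imputation from the model's stored reference.
    """
    model_list = [models] if isinstance(models, TransitionModel) else list(models)
    predictions: list[RiskPrediction] = []
    n_skipped = 0
    for sid, grp in panel.iter_subjects():
        negative = grp[grp["state"] != ABSORBING_STATE]
        if negative.empty or grp["state"].iloc[-1] == ABSORBING_STATE:
            n_skipped += 1
            continue
        row = negative.iloc[-1]
        covariates = {c: row[c] for c in panel.covariate_columns}
        predictions.append(
            predict_subject(
                model_list,
                sid,
                int(row["state"]),
                covariates,
                threshold=threshold,
                horizons=horizons,
            )
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} subject(s) already screen-positive")
    return predictions, n_skipped


def predictions_to_frame(predictions: Sequence[RiskPrediction]) -> pd.DataFrame:
    """Tabulate predictions for CSV export."""
    rows = []
    for p in predictions:
        row = {"subject_id": p.subject_id, "state": p.state}
        for h in sorted(p.risks):
            row[f"risk_{int(round(h * 12))}m"] = p.risks[h]
        row["interval_months"] = p.interval_months
        row["threshold"] = p.threshold
        row["imputed_flags"] = ";".join(p.imputed)
        rows.append(row)
    return pd.DataFrame(rows)
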