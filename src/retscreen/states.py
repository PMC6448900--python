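"""Disease-state space of the retinopathy progression model.

Four person-level states, graded from screening photographs:

1. no diabetic retinopathy detected
2. non-referable retinopathy in one eye
3. non-referable retinopathy in both eyes
4. referable retinopathy (screen-positive) — absorbing

Only six instantaneous moves are permitted: progression/regression between
adjacent non-referable states, plus entry into the absorbing screen-positive
state from states 2 and 3.  Observed panel jumps such as 1 -> 3 over a
screening interval are legal; they occur through intermediate states between
visits.
"""

from __future__ import annotations

N_STATES = 4
ABSORBING_STATE = 4
TRANSIENT_STATES = (1, 2, 3)

#: Permitted instantaneous transitions, in canonical order.  Every coefficient
#: vector in the model follows this ordering.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2),
    (2, 1),
    (2, 3),
    (2, 4),
    (3, 2),
    (3, 4),
)

#: The five clinical covariates of the progression model, in canonical order.
COVARIATES: tuple[str, ...] = (
    "age_at_diagnosis",
    "disease_duration",
    "hba1c",
    "systolic_bp",
    "total_cholesterol",
)

#: Units, for summaries and file headers.
COVARIATE_UNITS = {
    "age_at_diagnosis": "years",
    "disease_duration": "years",
    "hba1c": "mmol/mol",
    "systolic_bp": "mmHg",
    "total_cholesterol": "mmol/l",
}


def transition_label(i: int, j: int) -> str:
    return f"{i}->{j}"


def is_permitted(i: int, j: int) -> bool:
    """Whether i -> j is a permitted instantaneous transition."""
    return (i, j) in TRANSITIONS
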