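"""Continuous-time Markov machinery: intensities, Weibull transition
probabilities and the interval-censored panel likelihood.

The progression model is a four-state continuous-time Markov chain that is
homogeneous in *operational time* u = t**alpha, where t is years since the
subject's first screen and alpha is the Weibull shape.  Transition
intensities are log-linear in centred covariates,

    log lambda_ij = beta0_ij + sum_C beta_C_ij * (C - center_C),

arranged into a generator matrix Q whose rows sum to zero (state 4 is
absorbing).  The probability of being in state j at time t2 given state i at
time t1 is the (i, j) entry of

    P(t1, t2) = expm(Q * (t2**alpha - t1**alpha)),

which reduces to expm(Q * t**alpha) from baseline.  alpha < 1 concentrates
transitions early in follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .states import COVARIATES, N_STATES, TRANSITIONS, transition_label

#: Zero-based (row, col) indices of the six permitted transitions.
TRANSITION_INDEX = tuple((i - 1, j - 1) for i, j in TRANSITIONS)

#: Lower bound on evaluated intensities, avoiding log(0) during optimisation.
INTENSITY_FLOOR = 1e-12


class MissingCovariateError(ValueError):
    """A covariate needed by the model is missing; impute before calling."""


@dataclass
class TransitionModel:
    """Parameters of the fitted progression model.

    Attributes
    ----------
    intercepts
        Length-6 array of baseline log-intensities, one per permitted
        transition in :data:`retscreen.states.TRANSITIONS` order.
    coefficients
        Mapping covariate name -> length-6 array of per-unit log hazard
        ratios (same transition order).  Only active covariates appear.
    alpha
        Weibull shape of the operational-time transform, shared by all six
        transitions; alpha = 1 recovers a time-homogeneous chain.
    centering
        Per-covariate constants subtracted before the log-linear predictor;
        conventionally the cohort means at first screening.
    worst_case
        Optional per-covariate 75th percentiles of baseline values, used to
        impute missing covariates at prediction time ("worst case").
    metadata
        Free-form fit provenance (log-likelihood, n_subjects, ...).
    """

    intercepts: np.ndarray
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.9
    centering: dict[str, float] = field(default_factory=dict)
    worst_case: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.intercepts.shape != (len(TRANSITIONS),):
            raise ValueError("intercepts must have one entry per permitted transition")
        self.coefficients = {
            k: np.asarray(v, dtype=float) for k, v in self.coefficients.items()
        }
        for name, vec in self.coefficients.items():
            if name not in COVARIATES:
                raise ValueError(f"unknown covariate {name!r}")
            if vec.shape != (len(TRANSITIONS),):
                raise ValueError(f"coefficients[{name!r}] must have length {len(TRANSITIONS)}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in COVARIATES if c in self.coefficients)

    def hazard_ratios(self) -> pd.DataFrame:
        """Per-unit hazard ratios exp(beta), transitions as rows."""
        idx = [transition_label(i, j) for i, j in TRANSITIONS]
        return pd.DataFrame(
            {name: np.exp(vec) for name, vec in self.coefficients.items()}, index=idx
        )

    def linear_predictor(self, covariates: Mapping[str, float]) -> np.ndarray:
        """Length-6 log-intensity vector for one covariate vector."""
        eta = self.intercepts.copy()
        for name, beta in self.coefficients.items():
            if name not in covariates or covariates[name] is None or np.isnan(covariates[name]):
                raise MissingCovariateError(
                    f"covariate {name!r} is missing; apply imputation before prediction"
                )
            eta = eta + beta * (float(covariates[name]) - self.centering.get(name, 0.0))
        return eta

    def intensities(self, covariates: Mapping[str, float]) -> np.ndarray:
        return np.maximum(np.exp(self.linear_predictor(covariates)), INTENSITY_FLOOR)

    def intensity_matrix(self, covariates: Mapping[str, float]) -> np.ndarray:
        return intensity_matrix_from_rates(self.intensities(covariates))


def intensity_matrix_from_rates(rates: np.ndarray) -> np.ndarray:
    """Assemble generator matrices from permitted-transition intensities.

    ``rates`` has shape (..., 6) in canonical transition order; the result has
    shape (..., 4, 4) with the permitted zero pattern and zero row sums.
    """
    rates = np.asarray(rates, dtype=float)
    Q = np.zeros(rates.shape[:-1] + (N_STATES, N_STATES))
    for k, (r, c) in enumerate(TRANSITION_INDEX):
        Q[..., r, c] = rates[..., k]
    diag = -Q.sum(axis=-1)
    idx = np.arange(N_STATES)
    Q[..., idx, idx] = diag
    return Q


def build_intensity_matrix(model: TransitionModel, covariates: Mapping[str, float]) -> np.ndarray:
    """Generator matrix Q for one subject's (complete) covariate vector."""
    return model.intensity_matrix(covariates)


# ---------------------------------------------------------------------------
# Matrix exponential
# ---------------------------------------------------------------------------

# Pade-7 numerator coefficients; accurate to double precision for 1-norm
# below ~0.95, extended by scaling and squaring above it.
_PADE7_B = (17297280.0, 8648640.0, 1995840.0, 277200.0, 25200.0, 1512.0, 56.0, 1.0)
_PADE7_THETA = 0.95


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small matrices (..., n, n).

    Scaling-and-squaring with a degree-7 Pade approximant; the scaling power
    is chosen from the largest 1-norm in the stack.  Intended for the 4x4
    generators of the progression model, where it is orders of magnitude
    faster than looping scipy's expm, and agrees with it to ~1e-13.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[-1]
    norm = float(np.abs(A).sum(axis=-2).max()) if A.size else 0.0
    s = 0
    if norm > _PADE7_THETA:
        s = int(np.ceil(np.log2(norm / _PADE7_THETA)))
        A = A / (2.0**s)
    ident = np.broadcast_to(np.eye(n), A.shape)
    b = _PADE7_B
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A4 @ A2
    U = A @ (b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * ident)
    V = b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * ident
    P = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        P = P @ P
        # inputs are generators scaled by elapsed time, so the exact result is
        # a stochastic matrix; clipping keeps repeated squaring from amplifying
        # the Pade approximation's tiny overshoots
        np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_probability(
    Q: np.ndarray, t1: float, t2: float, alpha: float
) -> np.ndarray:
    """Interval transition-probability matrix P(t1, t2) = expm(Q (t2^a - t1^a)).

    ``t1`` and ``t2`` are years from the subject's baseline screen; for
    ``t1 = 0`` this is the baseline form expm(Q t^alpha).  Entries are clipped
    to [0, 1] after verifying the numerical overshoot is negligible.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if t1 < 0 or t2 < t1:
        raise ValueError(f"need 0 <= t1 <= t2, got t1={t1}, t2={t2}")
    Q = np.asarray(Q, dtype=float)
    du = t2**alpha - t1**alpha
    P = expm_batch(Q * du)
    overshoot = max(float((-P).max()), float((P - 1.0).max()), 0.0)
    if overshoot > 1e-9:
        warnings.warn(f"transition probabilities overshoot [0,1] by {overshoot:.2e}")
    return np.clip(P, 0.0, 1.0)


def state_occupancy(Q: np.ndarray, t: float, alpha: float, start_state: int) -> np.ndarray:
    """Probability distribution over the four states at time t from baseline."""
    if start_state not in range(1, N_STATES + 1):
        raise ValueError(f"start_state must be in 1..{N_STATES}")
    return transition_probability(Q, 0.0, t, alpha)[start_state - 1]


# ---------------------------------------------------------------------------
# Interval table and panel likelihood
# ---------------------------------------------------------------------------


@dataclass
class IntervalTable:
    """Flat arrays describing every observed interval of a panel dataset.

    One entry per consecutive episode pair within a subject: interval
    endpoints (years from that subject's baseline), states at both ends, the
    covariate values at the left endpoint (piecewise-constant convention)
    and the owning subject.
    """

    t1: np.ndarray
    t2: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    X: np.ndarray  # (n_intervals, n_covariates), raw (uncentred)
    covariate_names: tuple[str, ...]
    subject_index: np.ndarray
    subject_ids: list[str]

    @property
    def n_intervals(self) -> int:
        return len(self.t1)


def build_interval_table(
    panel,
    covariate_names: tuple[str, ...] = (),
    duration_fixed_at_baseline: bool = True,
) -> IntervalTable:
    """Extract the likelihood's interval table from a panel dataset.

    Covariates enter each interval at their left-endpoint value; with
    ``duration_fixed_at_baseline`` (default) disease duration is carried at
    its first-episode value throughout, matching assignment at the first
    screening episode.
    """
    f = panel.frame
    for cov in covariate_names:
        if cov not in f.columns:
            raise MissingCovariateError(f"panel has no column for covariate {cov!r}")
    sid = f["subject_id"].to_numpy()
    codes, uniques = pd.factorize(f["subject_id"], sort=False)
    t = f["time_years"].to_numpy()
    s = f["state"].to_numpy()
    same_subject = codes[1:] == codes[:-1]
    left = np.flatnonzero(same_subject)
    right = left + 1
    X = np.empty((len(left), len(covariate_names)))
    for k, cov in enumerate(covariate_names):
        col = f[cov].to_numpy(dtype=float)
        if cov == "disease_duration" and duration_fixed_at_baseline:
            first_rows = np.flatnonzero(np.r_[True, ~same_subject])
            col = col[first_rows][codes]
        X[:, k] = col[left]
    if np.isnan(X).any():
        bad = np.flatnonzero(np.isnan(X).any(axis=1))[0]
        raise MissingCovariateError(
            f"missing covariate value at an interval of subject {sid[left[bad]]!r}; "
            "run imputation before fitting or prediction"
        )
    return IntervalTable(
        t1=t[left],
        t2=t[right],
        s1=s[left],
        s2=s[right],
        X=X,
        covariate_names=tuple(covariate_names),
        subject_index=codes[left],
        subject_ids=list(uniques),
    )


def interval_log_probabilities(
    table: IntervalTable,
    intercepts: np.ndarray,
    coefficients: Mapping[str, np.ndarray],
    alpha: float,
    centering: Mapping[str, float],
) -> np.ndarray:
    """Log probability of each observed interval under the model."""
    eta = np.tile(np.asarray(intercepts, float), (table.n_intervals, 1))
    for k, cov in enumerate(table.covariate_names):
        if cov in coefficients:
            eta += np.outer(table.X[:, k] - centering.get(cov, 0.0), coefficients[cov])
    rates = np.maximum(np.exp(eta), INTENSITY_FLOOR)
    du = table.t2**alpha - table.t1**alpha
    A = intensity_matrix_from_rates(rates) * du[:, None, None]
    P = expm_batch(A)
    p_obs = P[np.arange(table.n_intervals), table.s1 - 1, table.s2 - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(np.clip(p_obs, 0.0, None))


def panel_log_likelihood(data, model: TransitionModel, duration_fixed_at_baseline: bool = True) -> float:
    """Interval-censored panel log-likelihood of a dataset under a model.

    Each consecutive episode pair contributes log P_{s1,s2}(t1, t2) with Q
    rebuilt from the covariates at the interval's left endpoint; arrival in
    the absorbing screen-positive state is interval-censored (its probability
    is simply the (s1, 4) entry of the interval matrix).  Returns -inf, with
    a warning naming the offending subjects, if any observed interval has
    zero probability under the model.
    """
    table = build_interval_table(data, model.covariate_names, duration_fixed_at_baseline)
    logp = interval_log_probabilities(
        table, model.intercepts, model.coefficients, model.alpha, model.centering
    )
    if np.any(np.isneginf(logp)):
        bad = np.unique(table.subject_index[np.isneginf(logp)])
        names = [table.subject_ids[b] for b in bad[:10]]
        warnings.warn(
            f"{np.isneginf(logp).sum()} interval(s) have zero probability "
            f"under the model (subjects {names}); log-likelihood is -inf"
        )
        return float("-inf")
    return float(logp.sum())
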