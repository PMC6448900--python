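"""Missing-covariate handling.

Two paths, matching how the engine is used:

* model fitting uses *multiple imputation* by chained equations (linear
  models with posterior-predictive draws), producing m completed copies of
  the panel that are fitted separately and pooled;
* deployed prediction uses a *worst-case* single imputation: each missing
  covariate is replaced by the 75th percentile of the cohort's baseline
  values, biasing the predicted risk upward rather than guessing low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .panel import PanelData
from .states import COVARIATES

#: Minimum completeness for a covariate to be imputable rather than excluded.
COMPLETENESS_THRESHOLD = 0.8


class CompletenessError(ValueError):
    """A covariate is below the completeness threshold; exclude it instead."""


def multiple_impute(
    panel: PanelData,
    m: int = 10,
    seed: int = 0,
    min_completeness: float = COMPLETENESS_THRESHOLD,
) -> list[PanelData]:
    """Chained-equations multiple imputation of missing covariates.

    Produces ``m`` completed copies of the panel.  Each copy is imputed by
    iterated Bayesian linear regressions over the covariate columns,
    conditioning also on the observed state and time (5 burn-in cycles,
    posterior-predictive noise), with an independent RNG stream per copy.
    Observed cells are never altered; results are deterministic given
    ``seed``.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2 copies")
    completeness = panel.completeness()
    low = {c: v for c, v in completeness.items() if v < min_completeness}
    if low:
        raise CompletenessError(
            f"covariates below {min_completeness:.0%} completeness: {low}; "
            "exclude them from the model instead of imputing"
        )
    cov_cols = list(panel.covariate_columns)
    if not panel.has_missing():
        return [PanelData(panel.frame, validate=False) for _ in range(m)]
    features = panel.frame[cov_cols + ["state", "time_years"]].to_numpy(dtype=float)
    child_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    copies = []
    for r in range(m):
        imputer = IterativeImputer(
            max_iter=5,
            sample_posterior=True,
            random_state=int(child_seeds[r]),
            keep_empty_features=True,
        )
        completed = imputer.fit_transform(features)
        frame = panel.frame.copy()
        for k, cov in enumerate(cov_cols):
            col = completed[:, k]
            # clip posterior draws into the physiological domain
            col = np.maximum(col, 0.0 if cov in ("age_at_diagnosis", "disease_duration") else 1e-6)
            frame[cov] = np.where(frame[cov].isna(), col, frame[cov])
        copies.append(PanelData(frame, validate=False))
    return copies


@dataclass(frozen=True)
class WorstCaseReference:
    """Per-covariate 75th percentiles of observed baseline values."""

    percentiles: Mapping[str, float]

    @classmethod
    def from_panel(cls, panel: PanelData, q: float = 75.0) -> "WorstCaseReference":
        """Compute the reference from non-missing first-episode values.

        Percentiles use linear interpolation between order statistics.
        """
        base = panel.baseline()
        ref = {}
        for cov in panel.covariate_columns:
            vals = base[cov].dropna().to_numpy()
            if len(vals) == 0:
                raise CompletenessError(f"no observed baseline values for {cov!r}")
            ref[cov] = float(np.percentile(vals, q, method="linear"))
        return cls(percentiles=ref)

    @classmethod
    def from_values(cls, percentiles: Mapping[str, float]) -> "WorstCaseReference":
        return cls(percentiles=dict(percentiles))


def worst_case_impute(
    covariates: Mapping[str, float], ref: WorstCaseReference
) -> dict[str, float]:
    """Replace missing entries by the stored 75th percentiles.

    Present values pass through untouched; the returned dict also records
    nothing about provenance — callers needing a flag should compare keys
    against the input's missing set (see :func:`missing_covariates`).
    """
    out = {}
    for cov in COVARIATES:
        if cov in covariates and covariates[cov] is not None and not np.isnan(covariates[cov]):
            out[cov] = float(covariates[cov])
        elif cov in ref.percentiles:
            out[cov] = float(ref.percentiles[cov])
    return out


def missing_covariates(covariates: Mapping[str, float], names=COVARIATES) -> tuple[str, ...]:
    """Names of covariates absent or NaN in a raw covariate mapping."""
    out = []
    for cov in names:
        v = covariates.get(cov)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(cov)
    return tuple(out)


def complete_panel_worst_case(panel: PanelData, ref: WorstCaseReference) -> PanelData:
    """Fill every missing covariate cell of a panel from the reference."""
    frame = panel.frame.copy()
    for cov in panel.covariate_columns:
        if cov in ref.percentiles:
            frame[cov] = frame[cov].fillna(ref.percentiles[cov])
    return PanelData(frame, validate=False)
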