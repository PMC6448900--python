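"""Nested covariate selection by Wald ranking and corrected AIC.

Candidates are ranked by their joint Wald statistic in the full model (all
candidates active); a sequence of nested models is then built by adding
covariates in rank order, starting from the retinopathy-state-only baseline.
The model with the smallest AICc is selected.  The resulting table reports,
per row, the newest covariate's Wald statistic, AICc, rescaled AICc
(AICc - min AICc, so the selected model scores 0) and the percentage of
explained likelihood relative to the baseline-to-full-model span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import RetinopathyMarkovModel, RetinopathyMarkovResults, aicc


def wald_statistic(fit: RetinopathyMarkovResults, covariate: str) -> float:
    """Joint Wald chi-square of one covariate's six transition coefficients."""
    stat, _, _ = fit.wald_test_covariate(covariate)
    return stat


def explained_likelihood(llf_k: float, llf_base: float, llf_full: float) -> float:
    """Percentage of the baseline-to-full log-likelihood span recovered.

    100 * (llf_k - llf_base) / (llf_full - llf_base); the baseline is the
    retinopathy-state-only model and the full model contains every candidate.
    """
    span = llf_full - llf_base
    if span == 0:
        raise ValueError("full and baseline models have identical log-likelihood")
    return 100.0 * (llf_k - llf_base) / span


@dataclass
class SelectionTable:
    """Outcome of the nested-model selection procedure."""

    table: pd.DataFrame
    selected: tuple[str, ...]
    fits: dict = field(default_factory=dict, repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select_covariates(
    panel,
    candidates: Sequence[str],
    fix_alpha: float | None = None,
    ranking: str = "joint",
    **fit_kwargs,
) -> SelectionTable:
    """Rank candidates, build nested models, pick the smallest AICc.

    Parameters
    ----------
    panel : PanelData
        Complete (imputed) panel dataset.
    candidates
        Covariate names to consider.
    ranking
        ``"joint"`` (default) ranks by each covariate's joint Wald statistic
        in the full model; ``"marginal"`` ranks by the Wald statistic of
        one-covariate-at-a-time fits.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate covariates supplied")

    def _fit(covs) -> RetinopathyMarkovResults:
        return RetinopathyMarkovModel(
            panel, covariates=covs, fix_alpha=fix_alpha
        ).fit(**fit_kwargs)

    full_fit = _fit(candidates)
    if ranking == "joint":
        wald = {c: wald_statistic(full_fit, c) for c in candidates}
    elif ranking == "marginal":
        wald = {c: wald_statistic(_fit([c]), c) for c in candidates}
    else:
        raise ValueError("ranking must be 'joint' or 'marginal'")
    order = sorted(candidates, key=lambda c: wald[c], reverse=True)

    base_fit = _fit([])
    llf_base, llf_full = base_fit.llf, full_fit.llf
    rows = [
        {
            "covariates": "baseline (retinopathy state only)",
            "newest": "",
            "wald": np.nan,
            "aicc": aicc(base_fit),
            "llf": llf_base,
            "explained_pct": explained_likelihood(llf_base, llf_base, llf_full),
            "failed": False,
        }
    ]
    fits = {"baseline": base_fit, "full": full_fit}
    active: list[str] = []
    for cov in order:
        active.append(cov)
        label = "+ " + cov
        try:
            fit_k = full_fit if len(active) == len(candidates) else _fit(list(active))
            rows.append(
                {
                    "covariates": label,
                    "newest": cov,
                    "wald": wald[cov],
                    "aicc": aicc(fit_k),
                    "llf": fit_k.llf,
                    "explained_pct": explained_likelihood(fit_k.llf, llf_base, llf_full),
                    "failed": False,
                }
            )
            fits[label] = fit_k
        except Exception as exc:  # noqa: BLE001 - procedure continues past a bad fit
            warnings.warn(f"nested fit {label!r} failed: {exc}")
            rows.append(
                {
                    "covariates": label,
                    "newest": cov,
                    "wald": wald[cov],
                    "aicc": np.nan,
                    "llf": np.nan,
                    "explained_pct": np.nan,
                    "failed": True,
                }
            )
    table = pd.DataFrame(rows)
    table["rescaled_aicc"] = table["aicc"] - table["aicc"].min()
    best = int(table["aicc"].idxmin())
    selected = tuple(order[:best]) if best > 0 else ()
    cols = ["covariates", "wald", "aicc", "rescaled_aicc", "explained_pct", "llf", "failed"]
    return SelectionTable(table=table[cols], selected=selected, fits=fits)
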