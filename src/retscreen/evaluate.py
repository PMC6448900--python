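"""Internal validation and screening-policy accounting.

Covers the two evaluation layers of the engine:

* discrimination — concordance index and fixed-horizon AUC / sensitivity /
  specificity of predicted screen-positive risks, with k-fold
  cross-validation and bootstrap optimism correction;
* policy accounting — how interval allocation at a risk threshold changes
  the number of screening episodes over two years versus an annual
  programme (episode multipliers 4x / 2x / 1x for 6 / 12 / 24 months), and
  correct / over- / under-allocation rates.

Screen-positive event times are interval-censored; the accounting uses the
midpoint of the last-negative-to-first-positive screening interval as the
event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import RetinopathyMarkovModel, RetinopathyMarkovResults
from .panel import PanelData
from .risk import DEFAULT_HORIZONS, DEFAULT_THRESHOLD
from .states import ABSORBING_STATE

#: Episode multipliers over a two-year period for the 6/12/24-month intervals.
EPISODE_MULTIPLIERS: dict[float, int] = {0.5: 4, 1.0: 2, 2.0: 1}

MAX_INTERVAL = 2.0  # years; the longest offered interval


# ---------------------------------------------------------------------------
# Outcome records
# ---------------------------------------------------------------------------


def outcomes_from_panel(panel: PanelData, use_exact_times: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject outcome records from observed screening episodes.

    Returns a frame with ``subject_id``, ``event`` (became screen-positive),
    and ``time``: the midpoint of the bracketing screening interval for
    positives, or the follow-up duration (last visit time) for negatives.
    With ``use_exact_times`` (a hidden-truth frame from the simulator,
    columns ``subject_id``/``time``/``state``), exact state-4 entry times
    replace the midpoint convention.
    """
    exact: dict[str, float] = {}
    if use_exact_times is not None:
        pos = use_exact_times[use_exact_times["state"] == ABSORBING_STATE]
        exact = dict(zip(pos["subject_id"].astype(str), pos["time"].astype(float)))
    rows = []
    for sid, grp in panel.iter_subjects():
        t = grp["time_years"].to_numpy()
        s = grp["state"].to_numpy()
        hit = np.flatnonzero(s == ABSORBING_STATE)
        if len(hit):
            k = hit[0]
            time = exact.get(sid, 0.5 * (t[k - 1] + t[k]))
            rows.append({"subject_id": sid, "event": True, "time": float(time)})
        else:
            rows.append({"subject_id": sid, "event": False, "time": float(t[-1])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Episode accounting (policy arithmetic)
# ---------------------------------------------------------------------------


@dataclass
class AllocationSummary:
    """Cohort-level interval counts and two-year episode arithmetic."""

    persons: dict[float, int]
    episodes: dict[float, int]
    total_episodes: int
    reference_episodes: int
    difference: int
    pct_difference: float
    empty_cohort: bool = False
    # proportion fields (filled by allocation_error_rates)
    positive_correct: float | None = None
    positive_overestimated: float | None = None
    negative_correct: float | None = None
    negative_underestimated: float | None = None
    n_positive: int | None = None
    n_negative: int | None = None
    n_excluded: int | None = None

    def as_series(self) -> pd.Series:
        d = {
            "persons_6m": self.persons.get(0.5, 0),
            "persons_12m": self.persons.get(1.0, 0),
            "persons_24m": self.persons.get(2.0, 0),
            "episodes_6m": self.episodes.get(0.5, 0),
            "episodes_12m": self.episodes.get(1.0, 0),
            "episodes_24m": self.episodes.get(2.0, 0),
            "total_episodes": self.total_episodes,
            "reference_episodes": self.reference_episodes,
            "difference": self.difference,
            "pct_difference": self.pct_difference,
        }
        for name in (
            "positive_correct",
            "positive_overestimated",
            "negative_correct",
            "negative_underestimated",
            "n_positive",
            "n_negative",
            "n_excluded",
        ):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.Series(d)


def episode_accounting(persons: Mapping[float, int]) -> AllocationSummary:
    """Two-year episode totals under the 4x/2x/1x multiplier rule.

    ``persons`` maps interval (years: 0.5, 1.0, 2.0) to the number of people
    allocated to it.  The annual reference is two episodes per person; the
    percent difference is relative to that reference.
    """
    persons = {float(h): int(n) for h, n in persons.items()}
    for h, n in persons.items():
        if h not in EPISODE_MULTIPLIERS:
            raise ValueError(f"unknown interval {h} years")
        if n < 0:
            raise ValueError(f"negative person count for interval {h}")
    episodes = {h: EPISODE_MULTIPLIERS[h] * persons.get(h, 0) for h in EPISODE_MULTIPLIERS}
    total = sum(episodes.values())
    n_people = sum(persons.values())
    reference = 2 * n_people
    empty = n_people == 0
    diff = total - reference
    pct = 0.0 if empty else 100.0 * diff / reference
    return AllocationSummary(
        persons=persons,
        episodes=episodes,
        total_episodes=total,
        reference_episodes=reference,
        difference=diff,
        pct_difference=pct,
        empty_cohort=empty,
    )


def allocation_error_rates(
    outcomes: pd.DataFrame,
    allocations: Mapping[str, float],
    max_interval: float = MAX_INTERVAL,
) -> AllocationSummary:
    """Correct/over/under-allocation proportions plus episode accounting.

    A screen-positive allocation is *correct* when the (midpoint) event time
    is at or after the allocated screening date, otherwise *overestimated*.
    A screen-negative allocation is *correct* only when the person received
    the maximal interval; anything shorter is *underestimated*.  Negatives
    with follow-up shorter than the maximal interval are excluded.  An
    annual programme is evaluated the same way with a fixed 12-month
    interval (so negatives are never correct by construction).
    """
    persons: dict[float, int] = {h: 0 for h in EPISODE_MULTIPLIERS}
    pos_total = pos_correct = 0
    neg_total = neg_correct = 0
    n_excluded = 0
    for rec in outcomes.itertuples(index=False):
        sid = str(rec.subject_id)
        if sid not in allocations:
            continue
        interval = float(allocations[sid])
        if interval not in persons:
            raise ValueError(f"allocation {interval} not an offered interval")
        if rec.event:
            if rec.time is None or np.isnan(rec.time):
                n_excluded += 1
                continue
            persons[interval] += 1
            pos_total += 1
            pos_correct += int(rec.time >= interval)
        else:
            if rec.time < max_interval:
                n_excluded += 1
                continue
            persons[interval] += 1
            neg_total += 1
            neg_correct += int(interval == max_interval)
    summary = episode_accounting(persons)
    summary.n_positive = pos_total
    summary.n_negative = neg_total
    summary.n_excluded = n_excluded
    if pos_total:
        summary.positive_correct = pos_correct / pos_total
        summary.positive_overestimated = 1.0 - summary.positive_correct
    if neg_total:
        summary.negative_correct = neg_correct / neg_total
        summary.negative_underestimated = 1.0 - summary.negative_correct
    return summary


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------


def concordance_index(
    scores: np.ndarray, event: np.ndarray, time: np.ndarray
) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly.

    A pair is comparable when one subject has an event strictly before the
    other's event-or-censoring time (or at the same time as a censoring).
    Concordant means the earlier-event subject has the higher predicted
    risk; tied scores count one half.
    """
    scores = np.asarray(scores, float)
    event = np.asarray(event, bool)
    time = np.asarray(time, float)
    num = den = 0.0
    for i in np.flatnonzero(event):
        comparable = (time > time[i]) | (~event & (time == time[i]))
        comparable[i] = False
        den += comparable.sum()
        num += np.sum(scores[i] > scores[comparable])
        num += 0.5 * np.sum(scores[i] == scores[comparable])
    if den == 0:
        raise ValueError("no comparable pairs; cannot compute concordance")
    return num / den


def horizon_discrimination(
    scores: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    horizon: float,
    threshold: float,
) -> dict[str, float]:
    """Fixed-horizon AUC, sensitivity and specificity of predicted risks.

    Positives had their event by the horizon; negatives were event-free
    through it (event or censoring after the horizon); subjects censored
    before the horizon are excluded.  Classification calls risk strictly
    above the threshold positive.
    """
    scores = np.asarray(scores, float)
    event = np.asarray(event, bool)
    time = np.asarray(time, float)
    pos = event & (time <= horizon)
    neg = time > horizon
    if not pos.any() or not neg.any():
        raise ValueError(f"one outcome class is empty at horizon {horizon}")
    keep = pos | neg
    y = pos[keep].astype(int)
    s = scores[keep]
    auc = float(roc_auc_score(y, s))
    sens = float(np.mean(s[y == 1] > threshold))
    spec = float(np.mean(s[y == 0] <= threshold))
    return {
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "n_positive": int(y.sum()),
        "n_negative": int(len(y) - y.sum()),
    }


def _bootstrap_auc_ci(
    scores, y, B: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    n = len(y)
    stats = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        stats.append(roc_auc_score(y[idx], scores[idx]))
    lo = (1 - level) / 2
    return float(np.quantile(stats, lo)), float(np.quantile(stats, 1 - lo))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Pooled held-out performance from subject-level cross-validation."""

    horizon_metrics: pd.DataFrame
    cindex: float
    fold_assignments: dict[str, int]
    k: int
    seed: int
    threshold: float
    predictions: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation (threshold {self.threshold:.1%})",
            f"held-out concordance index: {self.cindex:.3f}",
            self.horizon_metrics.to_string(),
        ]
        return "\n".join(lines)


def _stratified_folds(
    panel: PanelData, k: int, rng: np.random.Generator, stratify: bool
) -> dict[str, int]:
    base = panel.baseline()
    assignments: dict[str, int] = {}
    if stratify:
        groups = [grp["subject_id"].tolist() for _, grp in base.groupby("state")]
    else:
        groups = [base["subject_id"].tolist()]
    offset = 0
    for ids in groups:
        ids = list(ids)
        rng.shuffle(ids)
        for pos, sid in enumerate(ids):
            assignments[sid] = (pos + offset) % k
        offset += len(ids)
    return assignments


def kfold_validate(
    panel: PanelData,
    k: int = 4,
    seed: int = 0,
    covariates: Sequence[str] | None = None,
    fix_alpha: float | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    stratify: bool = True,
    min_events_per_fold: int = 5,
    ci_bootstrap: int = 200,
    truth: pd.DataFrame | None = None,
    **fit_kwargs,
) -> ValidationReport:
    """Subject-level k-fold cross-validation of the fitted engine.

    Folds are random at subject level, stratified by baseline state.  For
    each fold the model is refitted on the remaining folds and horizon risks
    are predicted for held-out subjects from their baseline episode; metrics
    are pooled over the union of held-out predictions.  Deterministic given
    ``seed``.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    outcomes = outcomes_from_panel(panel, use_exact_times=truth)
    n_events = int(outcomes["event"].sum())
    if n_events < min_events_per_fold * k:
        raise ValueError(
            f"only {n_events} screen-positive events for {k} folds "
            f"(need >= {min_events_per_fold} per fold); use fewer folds"
        )
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(panel, k, rng, stratify)
    fold_of = pd.Series(folds)
    pred_rows = []
    for fold in range(k):
        train_ids = fold_of.index[fold_of != fold]
        test_ids = fold_of.index[fold_of == fold]
        fit = RetinopathyMarkovModel(
            panel.subset(train_ids), covariates=covariates, fix_alpha=fix_alpha
        ).fit(**{"compute_cov": False, **fit_kwargs})
        tm = fit.transition_model()
        test_base = panel.subset(test_ids).baseline()
        from .risk import predict_subject  # local import avoids cycle at module load

        for row in test_base.itertuples(index=False):
            covs = {c: getattr(row, c) for c in panel.covariate_columns}
            pred = predict_subject(
                tm, row.subject_id, int(row.state), covs,
                threshold=threshold, horizons=horizons,
            )
            rec = {"subject_id": str(row.subject_id), "fold": fold}
            for h in horizons:
                rec[f"risk_{h}"] = pred.risks[float(h)]
            pred_rows.append(rec)
    preds = pd.DataFrame(pred_rows).merge(outcomes, on="subject_id")
    event = preds["event"].to_numpy(bool)
    time = preds["time"].to_numpy(float)
    metric_rows = []
    for h in horizons:
        s = preds[f"risk_{h}"].to_numpy(float)
        m = horizon_discrimination(s, event, time, float(h), threshold)
        pos = event & (time <= h)
        neg = time > h
        keep = pos | neg
        lo, hi = _bootstrap_auc_ci(
            s[keep], pos[keep].astype(int), ci_bootstrap, rng
        )
        m.update({"horizon": float(h), "auc_lo": lo, "auc_hi": hi})
        metric_rows.append(m)
    score = preds[f"risk_{max(horizons)}"].to_numpy(float)
    cindex = concordance_index(score, event, time)
    return ValidationReport(
        horizon_metrics=pd.DataFrame(metric_rows).set_index("horizon"),
        cindex=float(cindex),
        fold_assignments=folds,
        k=k,
        seed=seed,
        threshold=threshold,
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# Bootstrap optimism
# ---------------------------------------------------------------------------


def bootstrap_optimism(
    panel: PanelData,
    metric: Callable[[RetinopathyMarkovResults, PanelData], float],
    B: int = 200,
    seed: int = 0,
    covariates: Sequence[str] | None = None,
    fix_alpha: float | None = None,
    **fit_kwargs,
) -> tuple[float, int]:
    """Bootstrap estimate of a metric's optimism.

    For each of ``B`` subject-level resamples: fit the model on the
    resample, evaluate ``metric(fit, resample) - metric(fit, panel)``.  The
    mean of these differences estimates how much apparent (training)
    performance overstates out-of-sample performance; subtract it from the
    apparent metric to correct.  Replicates whose fit or metric fails are
    dropped and counted.  Deterministic given ``seed``.
    """
    if B < 50:
        raise ValueError("optimism estimation needs B >= 50 resamples")
    rng = np.random.default_rng(seed)
    ids = panel.subject_ids
    diffs = []
    n_failed = 0
    for _ in range(B):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for r, sid in enumerate(chosen):
            g = panel.frame[panel.frame["subject_id"] == sid].copy()
            g["subject_id"] = f"{sid}#rep{r}"
            frames.append(g)
        resample = PanelData(pd.concat(frames, ignore_index=True), validate=False)
        kw = {"compute_cov": False, "raise_on_fail": False, **fit_kwargs}
        try:
            fit = RetinopathyMarkovModel(
                resample, covariates=covariates, fix_alpha=fix_alpha
            ).fit(**kw)
            diffs.append(metric(fit, resample) - metric(fit, panel))
        except Exception as exc:  # noqa: BLE001 - replicate dropped, counted
            n_failed += 1
            warnings.warn(f"bootstrap replicate failed: {exc}")
    if not diffs:
        raise RuntimeError("all bootstrap replicates failed")
    return float(np.mean(diffs)), n_failed


def apparent_cindex(fit: RetinopathyMarkovResults, panel: PanelData) -> float:
    """C-index of a fitted model evaluated on a panel (2-year risk score)."""
    tm = fit.transition_model()
    # score every subject, including those ending screen-positive, from baseline
    from .risk import predict_subject

    outcomes = outcomes_from_panel(panel)
    base = panel.baseline().set_index("subject_id")
    scores = []
    for rec in outcomes.itertuples(index=False):
        row = base.loc[str(rec.subject_id)]
        covs = {c: row[c] for c in panel.covariate_columns}
        p = predict_subject(tm, str(rec.subject_id), int(row["state"]), covs)
        scores.append(p.risks[MAX_INTERVAL])
    return concordance_index(
        np.array(scores), outcomes["event"].to_numpy(bool), outcomes["time"].to_numpy(float)
    )


def optimism_corrected_cindex(
    panel: PanelData,
    B: int = 200,
    seed: int = 0,
    covariates: Sequence[str] | None = None,
    fix_alpha: float | None = None,
    **fit_kwargs,
) -> dict[str, float]:
    """Apparent, optimism and corrected C-index for a cohort."""
    fit = RetinopathyMarkovModel(panel, covariates=covariates, fix_alpha=fix_alpha).fit(
        **{"compute_cov": False, **fit_kwargs}
    )
    apparent = apparent_cindex(fit, panel)
    optimism, n_failed = bootstrap_optimism(
        panel, apparent_cindex, B=B, seed=seed, covariates=covariates,
        fix_alpha=fix_alpha, **fit_kwargs,
    )
    return {
        "apparent": apparent,
        "optimism": optimism,
        "corrected": apparent - optimism,
        "n_failed": n_failed,
    }
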