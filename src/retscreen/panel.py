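"""Screening-cohort panel data: schema, validation and CSV round-trip.

A panel dataset holds one row per screening episode: an opaque subject id,
time in years since that subject's first screen, the observed disease state
(1-4) and the clinical covariate values recorded nearest to (and before) the
episode.  Transition times are never observed directly — the process is only
sampled at visits — which is what makes the data interval-censored.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import ABSORBING_STATE, COVARIATES, N_STATES

REQUIRED_COLUMNS = ("subject_id", "time_years", "state")


class PanelSchemaError(ValueError):
    """The file or frame does not conform to the panel schema."""


class PanelIntegrityError(ValueError):
    """The data violate a structural invariant of the screening process."""


class PanelData:
    """Validated per-subject sequences of (time, state, covariates).

    Parameters
    ----------
    frame
        One row per episode with columns ``subject_id``, ``time_years``,
        ``state`` and any subset of the five covariate columns.  Missing
        covariate values are NaN.
    validate
        Check invariants on construction (default).  Each subject must start
        at time 0 in a screen-negative state (1-3), have at least two
        episodes with strictly increasing times, and never leave state 4.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy()
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise PanelSchemaError(f"missing required columns: {missing_cols}")
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["time_years"] = frame["time_years"].astype(float)
        state_float = frame["state"].astype(float)
        if not np.all(np.isfinite(state_float)) or np.any(state_float != np.round(state_float)):
            raise PanelSchemaError("state column must contain integers")
        frame["state"] = state_float.astype(int)
        for cov in COVARIATES:
            if cov in frame.columns:
                frame[cov] = frame[cov].astype(float)
        frame = frame.sort_values(["subject_id", "time_years"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        self.frame = frame
        self.covariate_columns: tuple[str, ...] = tuple(
            c for c in COVARIATES if c in frame.columns
        )
        if validate:
            self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        f = self.frame
        bad_state = f.loc[(f["state"] < 1) | (f["state"] > N_STATES)]
        if len(bad_state):
            sid = bad_state["subject_id"].iloc[0]
            raise PanelSchemaError(
                f"subject {sid!r}: state {bad_state['state'].iloc[0]} outside 1..{N_STATES}"
            )
        for cov in self.covariate_columns:
            vals = f[cov].to_numpy()
            observed = vals[~np.isnan(vals)]
            if np.any(~np.isfinite(observed)):
                raise PanelSchemaError(f"covariate {cov} has non-finite values")
            if cov in ("age_at_diagnosis", "disease_duration"):
                if np.any(observed < 0):
                    raise PanelSchemaError(f"covariate {cov} has negative values")
            elif np.any(observed <= 0):
                raise PanelSchemaError(f"covariate {cov} has non-positive values")
        for sid, grp in f.groupby("subject_id", sort=False):
            t = grp["time_years"].to_numpy()
            s = grp["state"].to_numpy()
            if len(grp) < 2:
                raise PanelIntegrityError(f"subject {sid!r}: fewer than two episodes")
            if t[0] != 0.0:
                raise PanelSchemaError(f"subject {sid!r}: first episode time is {t[0]}, not 0")
            if np.any(np.diff(t) <= 0):
                raise PanelSchemaError(f"subject {sid!r}: times not strictly increasing")
            if s[0] == ABSORBING_STATE:
                raise PanelIntegrityError(
                    f"subject {sid!r}: first observed state is {ABSORBING_STATE} "
                    "(cohort must be screen-negative at baseline)"
                )
            reached = np.flatnonzero(s == ABSORBING_STATE)
            if len(reached) and np.any(s[reached[0]:] != ABSORBING_STATE):
                raise PanelIntegrityError(
                    f"subject {sid!r}: leaves absorbing state {ABSORBING_STATE}"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def n_episodes(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def iter_subjects(self) -> Iterator[tuple[str, pd.DataFrame]]:
        yield from self.frame.groupby("subject_id", sort=False)

    def baseline(self) -> pd.DataFrame:
        """First (time-0) episode of every subject."""
        return self.frame.groupby("subject_id", sort=False).head(1)

    def subset(self, subject_ids: Sequence[str]) -> "PanelData":
        keep = self.frame["subject_id"].isin(set(subject_ids))
        return PanelData(self.frame.loc[keep], validate=False)

    def covariate_summary(self) -> pd.DataFrame:
        """Cohort-level summary of baseline covariates (mean, sd, quartiles)."""
        base = self.baseline()
        rows = {}
        for cov in self.covariate_columns:
            vals = base[cov].dropna()
            rows[cov] = {
                "mean": vals.mean(),
                "sd": vals.std(),
                "p25": vals.quantile(0.25),
                "p50": vals.quantile(0.50),
                "p75": vals.quantile(0.75),
                "n_observed": len(vals),
            }
        return pd.DataFrame(rows).T

    def completeness(self) -> dict[str, float]:
        """Fraction of non-missing cells per covariate column."""
        return {
            cov: float(1.0 - self.frame[cov].isna().mean())
            for cov in self.covariate_columns
        }

    def has_missing(self) -> bool:
        return any(self.frame[c].isna().any() for c in self.covariate_columns)

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        write_panel(self, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PanelData: {self.n_subjects} subjects, {self.n_episodes} episodes, "
            f"covariates={list(self.covariate_columns)}>"
        )


def read_panel(path, schema: Mapping[str, str] | None = None) -> PanelData:
    """Read a screening panel from delimited text.

    Parameters
    ----------
    path
        CSV file with a header row.  Canonical column names are
        ``subject_id``, ``time_years``, ``state`` plus covariate columns;
        empty cells are missing values.
    schema
        Optional mapping from canonical names to the file's column names,
        e.g. ``{"subject_id": "nhs_id"}``.
    """
    try:
        raw = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelSchemaError(f"cannot parse {path}: {exc}") from exc
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        raw = raw.rename(columns=rename)
    return PanelData(raw)


def write_panel(panel: PanelData, path) -> None:
    """Write a panel to CSV (canonical column order, empty cell = missing)."""
    cols = list(REQUIRED_COLUMNS) + list(panel.covariate_columns)
    panel.frame[cols].to_csv(path, index=False)
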