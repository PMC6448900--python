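"""Flat key/value text serialisation of fitted models.

One line per quantity, ``key = value``; full double precision; covariate
centering constants and the worst-case imputation percentiles travel with
the parameters so a deployed model file is self-contained.
"""

from __future__ import annotations

import numpy as np

from .markov import TransitionModel
from .states import COVARIATES, TRANSITIONS, transition_label

FORMAT_TAG = "retscreen-model-v1"


class ModelFileError(ValueError):
    """Malformed or incomplete model file."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_model(model: TransitionModel, path) -> None:
    """Serialise a model to a flat key/value text file."""
    lines = [f"format = {FORMAT_TAG}", f"alpha = {_fmt(model.alpha)}"]
    for k, (i, j) in enumerate(TRANSITIONS):
        lines.append(f"intercept {transition_label(i, j)} = {_fmt(model.intercepts[k])}")
    for cov in model.covariate_names:
        for k, (i, j) in enumerate(TRANSITIONS):
            lines.append(
                f"coef {transition_label(i, j)} {cov} = {_fmt(model.coefficients[cov][k])}"
            )
    for cov, val in model.centering.items():
        lines.append(f"center {cov} = {_fmt(val)}")
    for cov, val in model.worst_case.items():
        lines.append(f"worstcase {cov} = {_fmt(val)}")
    for key, val in model.metadata.items():
        lines.append(f"meta {key} = {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model(path) -> TransitionModel:
    """Parse a model file written by :func:`write_model` (lossless)."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ModelFileError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
    if entries.get("format") != FORMAT_TAG:
        raise ModelFileError(f"not a {FORMAT_TAG} file")
    if "alpha" not in entries:
        raise ModelFileError("model file is missing the Weibull shape 'alpha'")
    try:
        alpha = float(entries.pop("alpha"))
    except ValueError as exc:
        raise ModelFileError(f"alpha is not a number: {exc}") from exc
    entries.pop("format", None)

    intercepts = np.full(len(TRANSITIONS), np.nan)
    coefficients: dict[str, np.ndarray] = {}
    centering: dict[str, float] = {}
    worst_case: dict[str, float] = {}
    metadata: dict[str, str] = {}
    labels = {transition_label(i, j): k for k, (i, j) in enumerate(TRANSITIONS)}
    for key, value in entries.items():
        parts = key.split()
        try:
            if parts[0] == "intercept" and len(parts) == 2:
                intercepts[labels[parts[1]]] = float(value)
            elif parts[0] == "coef" and len(parts) == 3:
                lab, cov = parts[1], parts[2]
                if cov not in COVARIATES:
                    raise ModelFileError(f"unknown covariate {cov!r}")
                coefficients.setdefault(cov, np.zeros(len(TRANSITIONS)))[labels[lab]] = float(value)
            elif parts[0] == "center" and len(parts) == 2:
                centering[parts[1]] = float(value)
            elif parts[0] == "worstcase" and len(parts) == 2:
                worst_case[parts[1]] = float(value)
            elif parts[0] == "meta":
                metadata[" ".join(parts[1:])] = value
            else:
                raise ModelFileError(f"unrecognised key {key!r}")
        except (KeyError, ValueError) as exc:
            raise ModelFileError(f"cannot parse entry {key!r} = {value!r}: {exc}") from exc
    if np.isnan(intercepts).any():
        missing = [lab for lab, k in labels.items() if np.isnan(intercepts[k])]
        raise ModelFileError(f"missing intercepts for transitions {missing}")
    return TransitionModel(
        intercepts=intercepts,
        coefficients=coefficients,
        alpha=alpha,
        centering=centering,
        worst_case=worst_case,
        metadata=metadata,
    )
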