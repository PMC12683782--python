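"""Evaluate base clocks on a beta matrix; epigenetic age acceleration.

Every linear clock is scored uniformly as ``intercept + w · beta`` on the
aligned, imputed matrix, followed by the clock's output transform.  No
per-clock bespoke preprocessing (standardization, renormalization) is
applied; betas go in as-is.

Epigenetic age acceleration (EAA) is the signed difference between a
sample's predicted epigenetic age and its chronological age, in years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StateError, UsageError
from .io import MethylationMatrix, align_to_clock
from .registry import ClockDefinition, ExternalPredictor, Transform

DEFAULT_ADULT_AGE = 20.0


@dataclass
class PredictionTable:
    """Per-sample, per-clock predicted ages in years.

    ``extra`` columns (EAA, chronological age) can be attached for
    serialization; they are kept separate from the clock columns.
    """

    ages: pd.DataFrame  # index: sample ids, columns: clock names
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.ages.to_numpy(dtype=float)).all():
            raise UsageError("prediction table contains non-finite ages")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ages.index)

    @property
    def clock_names(self) -> list[str]:
        return list(self.ages.columns)

    def to_frame(self) -> pd.DataFrame:
        if self.extra is not None:
            return pd.concat([self.ages, self.extra], axis=1)
        return self.ages.copy()


@dataclass
class AgeAccelerationVector:
    """Signed EAA per sample: predicted minus chronological age (years)."""

    eaa: pd.Series  # index: sample ids; NaN where chronological age absent

    @property
    def sample_ids(self) -> list[str]:
        return list(self.eaa.index)


def horvath_inverse_transform(
    x: float | np.ndarray, adult_age: float = DEFAULT_ADULT_AGE
) -> float | np.ndarray:
    """Map a pan-tissue clock's linear score to age in years.

    Piecewise, continuous at 0:  exp branch ``(1+a)·e^x − 1`` for x < 0
    (childhood, log-compressed ages) and linear branch ``(1+a)·x + a``
    for x >= 0, with adult-age constant ``a`` (default 20).
    """
    if adult_age <= 0:
        raise UsageError("adult_age must be positive")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise UsageError("non-finite linear score")
    out = np.where(
        x < 0,
        (1.0 + adult_age) * np.exp(x) - 1.0,
        (1.0 + adult_age) * x + adult_age,
    )
    return float(out) if out.ndim == 0 else out


def horvath_forward_transform(
    age: float | np.ndarray, adult_age: float = DEFAULT_ADULT_AGE
) -> float | np.ndarray:
    """Inverse of :func:`horvath_inverse_transform` (age years -> score)."""
    age = np.asarray(age, dtype=float)
    out = np.where(
        age < adult_age,
        np.log(age + 1.0) - np.log(adult_age + 1.0),
        (age - adult_age) / (1.0 + adult_age),
    )
    return float(out) if out.ndim == 0 else out


def _apply_transform(score: np.ndarray, transform: Transform) -> np.ndarray:
    if transform is Transform.identity:
        return score
    if transform is Transform.horvath_log_linear:
        return np.asarray(horvath_inverse_transform(score))
    raise UsageError(f"unknown transform {transform!r}")


def predict_linear_clock(
    matrix: MethylationMatrix, clock: ClockDefinition
) -> pd.Series:
    """Ages (years) for every sample under one linear clock.

    The matrix is aligned to the clock's CpGs internally; it must already
    be imputed over them — residual missing values raise
    :class:`StateError` rather than silently biasing the dot product.
    """
    aligned = align_to_clock(matrix, clock).matrix
    vals = aligned.betas.to_numpy(dtype=float)
    if np.isnan(vals).any():
        n = int(np.isnan(vals).any(axis=0).sum())
        raise StateError(
            f"clock {clock.name!r}: {n} required CpG(s) still missing; "
            "run imputation first"
        )
    score = clock.intercept + vals @ clock.weights
    ages = _apply_transform(score, clock.transform)
    return pd.Series(ages, index=aligned.betas.index, name=clock.name)


def predict_external(
    matrix: MethylationMatrix, predictor: ExternalPredictor
) -> pd.Series:
    """Ages from a pluggable (non-linear) base predictor."""
    cols = list(predictor.cpg_ids)
    sub = matrix.betas.reindex(columns=cols)
    if sub.isna().to_numpy().any():
        raise StateError(
            f"external predictor {predictor.name!r}: missing CpGs; "
            "run imputation first"
        )
    try:
        ages = np.asarray(predictor.fn(sub), dtype=float)
    except Exception as exc:  # propagate with clock name attached
        raise UsageError(
            f"external predictor {predictor.name!r} failed: {exc}"
        ) from exc
    if ages.shape != (sub.shape[0],):
        raise UsageError(
            f"external predictor {predictor.name!r} returned shape "
            f"{ages.shape}, expected ({sub.shape[0]},)"
        )
    return pd.Series(ages, index=sub.index, name=predictor.name)


def predict_all(
    matrix: MethylationMatrix,
    clocks: Sequence[ClockDefinition | ExternalPredictor],
) -> PredictionTable:
    """One prediction column per clock, in registry order."""
    if len(clocks) == 0:
        raise UsageError("no clocks supplied")
    cols = []
    for clock in clocks:
        if isinstance(clock, ExternalPredictor):
            cols.append(predict_external(matrix, clock))
        else:
            cols.append(predict_linear_clock(matrix, clock))
    return PredictionTable(ages=pd.concat(cols, axis=1))


def epigenetic_age_acceleration(
    predicted: pd.Series, chronological: pd.Series
) -> AgeAccelerationVector:
    """EAA_i = predicted_i − chronological_i (years, signed).

    Samples with no chronological age get NaN EAA.
    """
    if len(predicted) != len(chronological):
        raise UsageError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(chronological)} chronological ages"
        )
    chron = pd.Series(
        np.asarray(chronological, dtype=float), index=predicted.index
    )
    return AgeAccelerationVector(eaa=predicted.astype(float) - chron)
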