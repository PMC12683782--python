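"""Missing-value imputation for beta matrices.

Missing CpG values are filled by round-robin multivariate regression:
each CpG column with missing entries is modelled as a Bayesian-ridge
regression on the other columns, starting from a column-mean initial fill
and refining over a fixed number of rounds (default 10, seed 0).  Columns
are visited in order of descending missing count, ties broken by id sort,
so results are deterministic.  Imputed values are clipped to [0, 1];
observed entries are never touched.

Imputation is applied at prediction time on the user's uploaded data, and
by default only over the union of the registered clocks' CpGs — the
columns prediction actually consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .errors import ImputationError
from .io import MethylationMatrix
from .registry import ClockDefinition, ExternalPredictor


class PredictorScope(str, Enum):
    clock_union = "clock_union"
    all_columns = "all_columns"


@dataclass(frozen=True)
class ImputerConfig:
    """Configuration for the round-robin regression imputer.

    ``max_iter`` refinement rounds (default 10) with ``seed`` (default 0)
    reproduce the published service configuration.
    """

    max_iter: int = 10
    seed: int = 0
    predictor_scope: PredictorScope = PredictorScope.clock_union

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


def impute(
    matrix: MethylationMatrix,
    config: ImputerConfig = ImputerConfig(),
    clocks: Sequence[ClockDefinition | ExternalPredictor] | None = None,
    prior_means: Mapping[str, float] | None = None,
) -> MethylationMatrix:
    """Return a copy of ``matrix`` with every missing beta filled in.

    Parameters
    ----------
    matrix : MethylationMatrix
        Input betas; NaN marks missing entries.
    config : ImputerConfig
        Rounds, seed and predictor scope.
    clocks : sequence of clocks, optional
        When ``predictor_scope`` is ``clock_union``, imputation runs over
        the intersection of the matrix columns with the union of these
        clocks' CpGs; other columns pass through untouched.
    prior_means : mapping CpG id -> beta, optional
        Fallback fill for columns with no observed value at all (e.g.
        reference means shipped alongside a clock).  Without a prior such
        a column raises :class:`ImputationError`.

    Notes
    -----
    With fewer than two samples there is no regression signal; columns
    fall back to their observed mean (i.e. the single observed value).
    Output is deterministic for a fixed ``(matrix, config)``.
    """
    df = matrix.betas.copy()

    if config.predictor_scope is PredictorScope.clock_union and clocks:
        union: set[str] = set()
        for c in clocks:
            union |= c.cpg_set
        scope_cols = [c for c in df.columns if c in union]
    else:
        scope_cols = list(df.columns)

    work = df[scope_cols]
    fully_missing = work.columns[work.isna().all(axis=0)]
    for col in fully_missing:
        if prior_means is not None and col in prior_means:
            df[col] = float(np.clip(prior_means[col], 0.0, 1.0))
        else:
            raise ImputationError(
                f"CpG {col!r} has no observed values and no prior mean"
            )
    work = df[scope_cols]

    if not work.isna().to_numpy().any():
        return MethylationMatrix(df)

    if work.shape[0] < 2:
        # single sample: no cross-sample regression possible; a column is
        # either observed or fully missing (handled above)
        raise ImputationError(
            "cannot impute a single-sample matrix with missing clock CpGs "
            "and no prior means"
        )

    imputer = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=config.max_iter,
        random_state=config.seed,
        initial_strategy="mean",
        imputation_order="descending",  # most-missing columns first
        sample_posterior=False,
        min_value=0.0,
        max_value=1.0,
        keep_empty_features=True,
        tol=0.0,  # fixed number of rounds, no early stopping
    )
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*Early stopping criterion not reached.*"
        )
        filled = imputer.fit_transform(work.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=work.index, columns=work.columns)
    # restore observed cells bit-exactly; keep only imputed predictions
    out = work.where(~work.isna(), out)
    df[scope_cols] = out
    return MethylationMatrix(df)


def mean_fill(matrix: MethylationMatrix) -> MethylationMatrix:
    """Baseline: fill each missing cell with its column's observed mean."""
    df = matrix.betas.copy()
    df = df.fillna(df.mean(axis=0))
    return MethylationMatrix(df)
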