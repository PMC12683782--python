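"""Ensemble stacking of base-clock predictions.

Two meta-models are provided:

* **EnsembleNaive** — uniform stacking: the arithmetic mean of a selected
  subset of base-clock predictions.  The default selection is six of the
  eight base clocks, excluding Hannum (large negative meta-weight, which
  a plain average cannot compensate) and PhenoAge (predicts phenotypic
  rather than biological age).
* **EnsembleLR** — dynamic stacking: an affine combination of all eight
  base predictions with weights learned by ridge regression (L2,
  alpha = 0.1) of chronological age on the base predictions, trained on
  an age-rebalanced cohort with an 80/20 split.

Age-group rebalancing uses SMOTE in methylation feature space *before*
base-clock prediction: a synthetic sample is drawn on the segment between
a minority-bin sample and one of its k nearest same-bin neighbours,
``x_new = x + u · (x_nn − x)`` with u ~ Uniform(0, 1), and its age is
interpolated with the same u.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import train_test_split

from .errors import StateError, UsageError
from .io import MethylationMatrix
from .predict import PredictionTable, predict_all
from .registry import ClockDefinition, ExternalPredictor

#: EnsembleNaive default: the six base clocks recommended for averaging
#: (Hannum and PhenoAge excluded).
DEFAULT_NAIVE_SELECTION = (
    "AltumAge",
    "Han2020",
    "Horvath",
    "SkinBlood",
    "YingCausAge",
    "Zhang2019",
)

#: Decade bins spanning the 20-80y range used for rebalancing.
DEFAULT_AGE_BIN_EDGES = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass(frozen=True)
class EnsembleLRModel:
    """Trained meta-model: age = intercept + Σ_c w_c · base_c."""

    clock_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    alpha: float = 0.1
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "clock_names", tuple(self.clock_names))
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=float)
        )
        if len(self.weights) != len(self.clock_names):
            raise UsageError(
                f"{len(self.clock_names)} clocks but "
                f"{len(self.weights)} weights"
            )
        if not (
            np.isfinite(self.weights).all() and np.isfinite(self.intercept)
        ):
            raise UsageError("non-finite meta-model parameters")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clock_names": list(self.clock_names),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleLRModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            clock_names=tuple(payload["clock_names"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            alpha=float(payload.get("alpha", 0.1)),
            provenance=payload.get("provenance", ""),
        )


def load_paper_model() -> EnsembleLRModel:
    """The packaged published EnsembleLR meta-model (read-only default)."""
    ref = resources.files("ensembleage.data") / "ensemble_lr_paper.json"
    with resources.as_file(ref) as path:
        return EnsembleLRModel.from_json(path)


def ensemble_naive(
    table: PredictionTable,
    selected: Sequence[str] | None = None,
) -> pd.Series:
    """Uniform stacking: per-sample mean over the selected clock columns."""
    names = (
        list(selected)
        if selected is not None
        else [c for c in DEFAULT_NAIVE_SELECTION if c in table.clock_names]
    )
    if len(names) == 0:
        raise UsageError("EnsembleNaive needs at least one selected clock")
    unknown = [n for n in names if n not in table.clock_names]
    if unknown:
        raise UsageError(f"unknown clock name(s) {unknown} in selection")
    out = table.ages[names].mean(axis=1)
    out.name = "EnsembleNaive"
    return out


def ensemble_lr_predict(
    table: PredictionTable, model: EnsembleLRModel
) -> pd.Series:
    """Dynamic stacking: intercept + weighted sum of base predictions.

    Columns are matched by clock *name*, never by position.
    """
    missing = [n for n in model.clock_names if n not in table.clock_names]
    if missing:
        raise UsageError(
            f"prediction table lacks clock column(s) {missing} "
            "required by the EnsembleLR model"
        )
    base = table.ages[list(model.clock_names)].to_numpy(dtype=float)
    out = pd.Series(
        model.intercept + base @ model.weights,
        index=table.ages.index,
        name="EnsembleLR",
    )
    return out


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE rebalancing parameters.

    ``age_bins`` are edges in years (default decades 20-80, last bin
    right-inclusive); ``target_count`` defaults to the largest observed
    bin count; ``k_neighbors`` same-bin candidates per interpolation.
    """

    k_neighbors: int = 5
    age_bins: tuple[float, ...] = DEFAULT_AGE_BIN_EDGES
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise UsageError("k_neighbors must be >= 1")
        edges = np.asarray(self.age_bins, dtype=float)
        if len(edges) < 2 or not (np.diff(edges) > 0).all():
            raise UsageError("age_bins must be strictly increasing edges")


def assign_age_bins(
    ages: pd.Series | np.ndarray, edges: Sequence[float]
) -> np.ndarray:
    """Bin index per sample; the last bin includes its right edge."""
    edges = np.asarray(edges, dtype=float)
    a = np.asarray(ages, dtype=float)
    if np.isnan(a).any():
        raise UsageError("cannot bin samples with missing ages")
    if (a < edges[0]).any() or (a > edges[-1]).any():
        raise UsageError(
            f"ages outside the bin range [{edges[0]}, {edges[-1]}]"
        )
    idx = np.digitize(a, edges, right=False) - 1
    return np.clip(idx, 0, len(edges) - 2)  # right edge into last bin


def smote_oversample(
    matrix: MethylationMatrix,
    ages: pd.Series,
    config: SmoteConfig = SmoteConfig(),
) -> tuple[MethylationMatrix, pd.Series, pd.Series]:
    """Rebalance age bins by convex interpolation in beta space.

    Returns ``(augmented_matrix, augmented_ages, synthetic_flags)`` where
    the flags Series is True for SMOTE-generated samples.  Synthetic betas
    are convex combinations of two real same-bin samples, hence stay in
    [0, 1]; ages are interpolated with the same mixing coefficient, so a
    synthetic age never leaves its parents' bin span.
    """
    df = matrix.betas
    if df.isna().to_numpy().any():
        raise StateError("SMOTE requires a fully observed (imputed) matrix")
    ages = pd.Series(np.asarray(ages, dtype=float), index=df.index)
    bins = assign_age_bins(ages, config.age_bins)
    n_bins = len(config.age_bins) - 1
    counts = np.bincount(bins, minlength=n_bins)
    target = (
        int(config.target_count)
        if config.target_count is not None
        else int(counts.max())
    )
    if target < counts.max():
        raise UsageError(
            f"target_count {target} below largest bin count {counts.max()}"
        )

    rng = np.random.default_rng(config.seed)
    X = df.to_numpy(dtype=float)
    new_rows, new_ages, new_ids = [], [], []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        deficit = target - len(members)
        if deficit <= 0:
            continue
        if len(members) == 0:
            warnings.warn(
                f"age bin {b} is empty; skipped by SMOTE", stacklevel=2
            )
            continue
        if len(members) == 1:
            warnings.warn(
                f"age bin {b} has a single sample; duplicating it",
                stacklevel=2,
            )
            for j in range(deficit):
                new_rows.append(X[members[0]].copy())
                new_ages.append(float(ages.iloc[members[0]]))
                new_ids.append(f"SMOTE_b{b}_{j}")
            continue
        k = config.k_neighbors
        if k > len(members) - 1:
            warnings.warn(
                f"age bin {b}: k_neighbors reduced to {len(members) - 1}",
                stacklevel=2,
            )
            k = len(members) - 1
        # pairwise distances within the bin, in methylation feature space
        sub = X[members]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]  # k nearest same-bin neighbours
        for j in range(deficit):
            i = rng.integers(len(members))
            mate = nn[i, rng.integers(k)]
            u = rng.uniform()
            new_rows.append(sub[i] + u * (sub[mate] - sub[i]))
            a_i = float(ages.iloc[members[i]])
            a_m = float(ages.iloc[members[mate]])
            new_ages.append(a_i + u * (a_m - a_i))
            new_ids.append(f"SMOTE_b{b}_{j}")

    if new_rows:
        aug = pd.DataFrame(
            np.vstack(new_rows), index=new_ids, columns=df.columns
        )
        out_df = pd.concat([df, aug])
        out_ages = pd.concat(
            [ages, pd.Series(new_ages, index=new_ids, dtype=float)]
        )
    else:
        out_df, out_ages = df.copy(), ages.copy()
    flags = pd.Series(False, index=df.index).reindex(
        out_df.index, fill_value=True
    )
    flags.name = "synthetic"
    return MethylationMatrix(out_df), out_ages, flags


def train_ensemble_lr(
    matrix: MethylationMatrix,
    ages: pd.Series,
    clocks: Sequence[ClockDefinition | ExternalPredictor],
    alpha: float = 0.1,
    split: float = 0.8,
    seed: int = 0,
    smote: SmoteConfig | None = None,
):
    """Train the EnsembleLR meta-model; evaluate on the held-out split.

    Pipeline: SMOTE rebalancing in beta space -> base-clock prediction on
    the augmented cohort -> seeded 80/20 split stratified by age bin ->
    ridge regression (penalty on weights only, unpenalized intercept,
    unstandardized features) of chronological age on the base predictions.

    Returns ``(EnsembleLRModel, EvaluationReport)`` where the report is
    computed on the held-out fraction.
    """
    from .evaluate import error_report  # local import avoids a cycle

    if len(clocks) == 0:
        raise UsageError("no base clocks supplied")
    if not 0 < split < 1:
        raise UsageError("split must be in (0, 1)")
    smote = smote if smote is not None else SmoteConfig(seed=seed)
    # rebalancing operates in the feature space prediction consumes:
    # the union of the base clocks' CpGs
    union: set[str] = set()
    for c in clocks:
        union |= c.cpg_set
    keep = [col for col in matrix.betas.columns if col in union]
    matrix = MethylationMatrix(matrix.betas[keep])
    aug_matrix, aug_ages, _ = smote_oversample(matrix, ages, smote)
    if aug_matrix.n_samples < 10 * len(clocks):
        raise UsageError(
            f"need >= {10 * len(clocks)} samples after oversampling, "
            f"got {aug_matrix.n_samples}"
        )
    table = predict_all(aug_matrix, clocks)
    X = table.ages.to_numpy(dtype=float)
    y = aug_ages.to_numpy(dtype=float)

    strata = assign_age_bins(aug_ages, smote.age_bins)
    occupied = np.bincount(strata)
    stratify = strata if occupied[occupied > 0].min() >= 2 else None
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, random_state=seed, stratify=stratify
    )

    ridge = Ridge(alpha=alpha, fit_intercept=True)
    ridge.fit(X[train_idx], y[train_idx])
    model = EnsembleLRModel(
        clock_names=tuple(table.clock_names),
        weights=ridge.coef_,
        intercept=float(ridge.intercept_),
        alpha=alpha,
        provenance=(
            f"user-trained: n={len(y)} (after SMOTE), split={split}, "
            f"alpha={alpha}, seed={seed}"
        ),
    )
    held_out_pred = pd.Series(
        model.intercept + X[test_idx] @ model.weights,
        index=table.ages.index[test_idx],
    )
    held_out_chron = pd.Series(y[test_idx], index=held_out_pred.index)
    report = error_report(held_out_pred, held_out_chron)
    return model, report
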