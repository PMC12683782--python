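"""End-to-end prediction workflow: read -> impute -> predict -> report.

This is the library-level analog of the hosted clock service: given a
beta CSV (and optional ages/groups), it evaluates every available base
clock, the uniform ensemble (EnsembleNaive) and the trained meta-model
(EnsembleLR), and writes a predictions CSV plus a JSON run manifest
recording seeds, model provenance, per-clock coverage and imputed-cell
counts, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    DEFAULT_NAIVE_SELECTION,
    EnsembleLRModel,
    ensemble_lr_predict,
    ensemble_naive,
    load_paper_model,
)
from .errors import ImputationError, UsageError
from .impute import ImputerConfig, impute
from .io import (
    MethylationMatrix,
    SampleMetadata,
    align_to_clock,
    read_beta_csv,
    read_metadata_csv,
)
from .predict import (
    PredictionTable,
    epigenetic_age_acceleration,
    predict_all,
)
from .registry import ClockDefinition, ExternalPredictor


@dataclass
class RunConfig:
    """Configuration of one prediction run."""

    input_path: Path
    clocks: Sequence[ClockDefinition | ExternalPredictor]
    metadata_path: Path | None = None
    model_choice: str = "paper"  # "paper" or a path to a trained JSON model
    naive_selection: Sequence[str] | None = None  # None -> recommended six
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    prior_means: Mapping[str, float] | None = None
    output_dir: Path = Path(".")

    def resolve_model(self) -> EnsembleLRModel:
        if self.model_choice == "paper":
            return load_paper_model()
        return EnsembleLRModel.from_json(self.model_choice)


def run_predict(config: RunConfig) -> pd.DataFrame:
    """Execute the workflow; returns the predictions frame it wrote.

    Clocks whose CpGs are entirely absent (or cannot be completed even by
    imputation) are reported as missing columns with a warning; each
    ensemble is computed only when every one of its inputs exists.
    """
    if len(config.clocks) == 0:
        raise UsageError("no clocks configured")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix = read_beta_csv(config.input_path)
    meta = (
        read_metadata_csv(config.metadata_path)
        if config.metadata_path is not None
        else None
    )

    coverage = {
        c.name: (
            align_to_clock(matrix, c).coverage
            if isinstance(c, ClockDefinition)
            else float(
                np.mean([p in matrix.betas.columns for p in c.cpg_ids])
            )
        )
        for c in config.clocks
    }
    n_missing_before = matrix.n_missing
    try:
        imputed = impute(
            matrix,
            config.imputer,
            clocks=config.clocks,
            prior_means=config.prior_means,
        )
    except ImputationError as exc:
        warnings.warn(
            f"imputation over observed columns incomplete: {exc}",
            stacklevel=2,
        )
        imputed = matrix

    columns: dict[str, pd.Series] = {}
    usable: list[ClockDefinition | ExternalPredictor] = []
    for clock in config.clocks:
        filled = _complete_for_clock(imputed, clock, config.prior_means)
        if filled is None:
            warnings.warn(
                f"clock {clock.name!r}: insufficient CpG coverage "
                f"({coverage[clock.name]:.3f}); reported as missing",
                stacklevel=2,
            )
            columns[clock.name] = pd.Series(
                np.nan, index=imputed.betas.index, name=clock.name
            )
            continue
        table_one = predict_all(filled, [clock])
        columns[clock.name] = table_one.ages[clock.name]
        usable.append(clock)

    frame = pd.DataFrame(columns, index=imputed.betas.index)

    usable_table = (
        PredictionTable(ages=frame[[c.name for c in usable]])
        if usable
        else None
    )
    naive_label = "EnsembleNaive"
    selection = (
        list(config.naive_selection)
        if config.naive_selection is not None
        else [
            n
            for n in DEFAULT_NAIVE_SELECTION
            if usable_table is not None and n in usable_table.clock_names
        ]
    )
    if config.naive_selection is not None and sorted(selection) != sorted(
        n for n in DEFAULT_NAIVE_SELECTION if n in frame.columns
    ):
        naive_label = "EnsembleNaive(custom)"
    if usable_table is not None and selection and all(
        s in usable_table.clock_names for s in selection
    ):
        frame[naive_label] = ensemble_naive(usable_table, selection)
    model = config.resolve_model()
    if usable_table is not None and all(
        n in usable_table.clock_names for n in model.clock_names
    ):
        frame["EnsembleLR"] = ensemble_lr_predict(usable_table, model)

    if meta is not None:
        ages = meta.ages_for(frame.index)
        frame["chronological_age"] = ages
        for col in [c for c in frame.columns if c != "chronological_age"]:
            if col.startswith("EnsembleNaive") or col in (
                "EnsembleLR",
                *[c.name for c in usable],
            ):
                eaa = epigenetic_age_acceleration(frame[col], ages)
                frame[f"EAA_{col}"] = eaa.eaa

    pred_path = out_dir / "predictions.csv"
    frame.index.name = "sample_id"
    frame.to_csv(pred_path, float_format="%.6f", na_rep="NA")

    manifest = {
        "package_version": __version__,
        "input": str(config.input_path),
        "metadata": (
            str(config.metadata_path) if config.metadata_path else None
        ),
        "n_samples": matrix.n_samples,
        "n_cpgs_input": matrix.n_cpgs,
        "imputer": {
            "max_iter": config.imputer.max_iter,
            "seed": config.imputer.seed,
            "predictor_scope": config.imputer.predictor_scope.value,
        },
        "imputed_cells": int(n_missing_before - imputed.n_missing),
        "coverage": coverage,
        "model": {
            "choice": config.model_choice,
            "provenance": model.provenance,
        },
        "naive_selection": selection,
        "columns": list(frame.columns),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return frame


def _complete_for_clock(
    matrix: MethylationMatrix,
    clock: ClockDefinition | ExternalPredictor,
    prior_means: Mapping[str, float] | None,
) -> MethylationMatrix | None:
    """Aligned, fully observed matrix for one clock, or None if impossible.

    Columns absent from the input can only be completed from prior means;
    without them the clock cannot be evaluated.
    """
    cols = list(clock.cpg_ids)
    sub = matrix.betas.reindex(columns=cols)
    if sub.isna().to_numpy().any():
        missing_cols = sub.columns[sub.isna().any(axis=0)]
        for col in missing_cols:
            if prior_means is not None and col in prior_means:
                sub[col] = sub[col].fillna(
                    float(np.clip(prior_means[col], 0.0, 1.0))
                )
        if sub.isna().to_numpy().any():
            return None
    return MethylationMatrix(sub)
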