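"""Beta-matrix and metadata I/O.

Input files are CpG-per-row CSV: the first column holds ``cg``-prefixed
probe ids, each subsequent column one sample's beta values (the
methylation ratio M/(M+U), already normalized to [0, 1]).  The two-column
case is a single-sample file.  The first line is treated as a header when
its first cell is not a cg id; headerless files get sample names S1..Sn.

Internally matrices are sample-major (samples x CpGs) because prediction
iterates over samples; missing entries are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, UsageError
from .registry import ClockDefinition

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta values in [0, 1], NaN for missing.

    Wraps a pandas DataFrame whose index is sample ids and whose columns
    are CpG probe ids.
    """

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.betas
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate CpG ids")
        vals = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise RangeError(
                f"beta value {vals[r, c]} out of [0,1] at sample "
                f"{df.index[r]!r}, CpG {df.columns[c]!r}"
            )
        self.betas = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.betas.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.betas.isna().to_numpy().sum())

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.betas.copy())


@dataclass
class SampleMetadata:
    """Per-sample chronological age (years) and optional group labels."""

    table: pd.DataFrame  # index: sample_id; columns: age, group, age_group

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        if "age" in self.table.columns:
            ages = pd.to_numeric(self.table["age"], errors="coerce")
            ok = ages.isna() | ((ages >= 0) & (ages <= 130))
            if not ok.all():
                bad = self.table.index[~ok][0]
                raise RangeError(
                    f"chronological age out of [0,130] for sample {bad!r}"
                )
            self.table = self.table.assign(age=ages)

    def ages_for(self, sample_ids: Iterable[str]) -> pd.Series:
        """Chronological ages aligned to the given samples (NaN if absent)."""
        if "age" not in self.table.columns:
            return pd.Series(np.nan, index=list(sample_ids), name="age")
        return self.table["age"].reindex(list(sample_ids))

    def groups_for(self, sample_ids: Iterable[str]) -> pd.Series:
        if "group" not in self.table.columns:
            return pd.Series(pd.NA, index=list(sample_ids), name="group")
        return self.table["group"].reindex(list(sample_ids))


def _looks_like_cg_id(token: str) -> bool:
    t = token.strip()
    return t.lower().startswith("cg") and t[2:].isdigit()


def read_beta_csv(path: str | Path) -> MethylationMatrix:
    """Read a CpG-per-row beta CSV into a sample-major matrix.

    Accepts both the single-sample (two-column) and multi-sample dialects.
    Empty cells and NA/NaN tokens parse as missing; values outside [0, 1]
    raise :class:`RangeError`.
    """
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1, dtype=str)
    has_header = not _looks_like_cg_id(str(first.iloc[0, 0]))
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        index_col=0,
        dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < 1:
        raise FormatError(f"{path}: need at least 2 columns (cgID + sample)")
    if not has_header:
        df.columns = [f"S{i + 1}" for i in range(df.shape[1])]
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate cgID row {dup!r}")

    as_str = df.astype(str)  # NaN -> "nan", always object dtype
    mask_missing = as_str.apply(
        lambda col: col.str.strip().str.lower().isin(_MISSING_TOKENS)
    )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mask_missing
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric beta {df.iat[r, c]!r} at "
            f"cgID {df.index[r]!r}"
        )
    # orient samples x CpGs
    return MethylationMatrix(numeric.T)


def write_beta_csv(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write the CpG-per-row dialect (columns: cgID then one per sample)."""
    out = matrix.betas.T
    out.index.name = "cgID"
    out.to_csv(path, float_format="%.17g", na_rep="NA")


def read_metadata_csv(path: str | Path) -> SampleMetadata:
    """Read sample metadata CSV with columns ``sample_id, age[, group]``."""
    df = pd.read_csv(path, dtype={0: str})
    cols = {c.lower().strip(): c for c in df.columns}
    if "sample_id" not in cols:
        raise FormatError(f"{path}: missing sample_id column")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df = df.set_index("sample_id")
    return SampleMetadata(df)


@dataclass
class AlignedMatrix:
    """A matrix restricted to one clock's CpGs, in clock order."""

    matrix: MethylationMatrix
    coverage: float  # fraction of clock CpGs present in the input


def align_to_clock(
    matrix: MethylationMatrix, clock: ClockDefinition
) -> AlignedMatrix:
    """Restrict to ``clock.cpg_ids`` in clock order.

    CpGs absent from the input become all-missing columns; nothing is ever
    fabricated.  Coverage is the fraction of clock CpGs present.
    """
    cols = list(clock.cpg_ids)
    present = sum(c in matrix.betas.columns for c in cols)
    sub = matrix.betas.reindex(columns=cols)
    return AlignedMatrix(
        matrix=MethylationMatrix(sub),
        coverage=present / len(cols),
    )


def write_predictions_csv(table, path: str | Path) -> None:
    """Write a per-sample, per-clock predictions table (6-dp round trip).

    ``table`` is a :class:`~ensembleage.predict.PredictionTable`; extra
    EAA columns, when attached, are written after the clock columns.
    """
    df = table.to_frame()
    if df.empty:
        raise UsageError("refusing to write an empty prediction table")
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.6f")


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
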