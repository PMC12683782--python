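"""Clock-quality metrics and cohort comparisons.

Accuracy is summarized by the median and mean absolute error between
predicted and chronological age (MeAE / MAE, years) and by the slope of
the best-fit line of predicted on chronological age — a slope of 1 with
intercept 0 is the ideal clock; systematic compression of the age range
shows up as slope < 1 even when MeAE looks acceptable.

Cohort contrasts compare mean epigenetic age acceleration (EAA) between
two groups with Welch's t-test (default) or the Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError
from .io import MethylationMatrix
from .predict import AgeAccelerationVector


@dataclass(frozen=True)
class EvaluationReport:
    """MeAE/MAE and best-fit line of predicted on chronological age."""

    n: int
    meae: float
    mae: float
    slope: float  # NaN when chronological age has zero variance
    fit_intercept: float
    pearson_r: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "meae": self.meae,
            "mae": self.mae,
            "slope": self.slope,
            "fit_intercept": self.fit_intercept,
            "pearson_r": self.pearson_r,
        }


@dataclass(frozen=True)
class GroupComparison:
    """Two-group EAA contrast: difference = mean(group2) − mean(group1)."""

    group_names: tuple[str, str]
    mean_eaa: tuple[float, float]
    difference: float
    p_value: float
    test_name: str
    n: tuple[int, int]
    low_power: bool = False


def error_report(
    predicted: pd.Series | np.ndarray, chronological: pd.Series | np.ndarray
) -> EvaluationReport:
    """MeAE, MAE, OLS slope/intercept and Pearson r of predicted vs true age.

    The best-fit line regresses predicted (y) on chronological (x) age.
    The median of an even-length error list is the mean of the two
    central values.  Samples with a missing chronological age are
    dropped.
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape:
        raise UsageError("predicted and chronological lengths differ")
    keep = ~np.isnan(c) & ~np.isnan(p)
    p, c = p[keep], c[keep]
    if len(p) < 1:
        raise UsageError("no samples with both predicted and true age")
    err = np.abs(p - c)
    meae = float(np.median(err))
    mae = float(np.mean(err))
    if len(p) >= 2 and np.ptp(c) > 0:
        fit = stats.linregress(c, p)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r = float(fit.rvalue) if np.ptp(p) > 0 else np.nan
    else:
        slope = intercept = r = float("nan")
    return EvaluationReport(
        n=len(p),
        meae=meae,
        mae=mae,
        slope=slope,
        fit_intercept=intercept,
        pearson_r=r,
    )


@dataclass(frozen=True)
class CpGAgeCorrelations:
    """Per-CpG Pearson correlation between beta and chronological age."""

    r: pd.Series  # index: CpG ids, sorted descending by r

    def top_positive(self, k: int = 4) -> pd.Series:
        return self.r.head(k)

    def top_negative(self, k: int = 4) -> pd.Series:
        return self.r.tail(k).iloc[::-1]


def per_cpg_age_correlation(
    matrix: MethylationMatrix, ages: pd.Series | np.ndarray
) -> CpGAgeCorrelations:
    """Pearson r between each CpG's betas and chronological age.

    Zero-variance CpG columns and columns with missing values are
    excluded; requires at least 3 samples.
    """
    ages = np.asarray(ages, dtype=float)
    df = matrix.betas
    if df.shape[0] < 3:
        raise UsageError("need at least 3 samples for correlation")
    if len(ages) != df.shape[0]:
        raise UsageError("ages length does not match sample count")
    complete = df.columns[df.notna().all(axis=0)]
    X = df[complete].to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any() or np.std(ages) == 0:
        warnings.warn(
            "no variable CpGs (or constant ages); empty correlation result",
            stacklevel=2,
        )
        return CpGAgeCorrelations(r=pd.Series(dtype=float))
    Xv = X[:, keep]
    xc = Xv - Xv.mean(axis=0)
    ac = ages - ages.mean()
    r = (xc.T @ ac) / (np.sqrt((xc**2).sum(axis=0)) * np.sqrt((ac**2).sum()))
    out = pd.Series(r, index=complete[keep], name="pearson_r")
    return CpGAgeCorrelations(r=out.sort_values(ascending=False))


def compare_groups_eaa(
    eaa: AgeAccelerationVector | pd.Series,
    labels: pd.Series | np.ndarray,
    test: Literal["welch", "mannwhitney"] = "welch",
) -> GroupComparison:
    """Compare mean EAA between exactly two groups.

    Reports per-group means, their difference (group2 − group1, groups in
    sorted label order), and the two-sided p-value from Welch's t-test or
    the Mann-Whitney U test.  Comparisons with fewer than 5 samples in a
    group are flagged ``low_power``.
    """
    vec = eaa.eaa if isinstance(eaa, AgeAccelerationVector) else eaa
    vals = np.asarray(vec, dtype=float)
    labs = np.asarray(labels)
    if len(vals) != len(labs):
        raise UsageError("EAA and label lengths differ")
    keep = ~np.isnan(vals)
    vals, labs = vals[keep], labs[keep]
    names = sorted(pd.unique(labs).tolist())
    if len(names) != 2:
        raise UsageError(
            f"exactly 2 groups required, got {len(names)}: {names}"
        )
    g1 = vals[labs == names[0]]
    g2 = vals[labs == names[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise UsageError("each group needs at least 2 samples")
    if test == "welch":
        stat = stats.ttest_ind(g2, g1, equal_var=False)
        p_value, test_name = float(stat.pvalue), "welch_t"
    elif test == "mannwhitney":
        stat = stats.mannwhitneyu(g2, g1, alternative="two-sided")
        p_value, test_name = float(stat.pvalue), "mannwhitney_u"
    else:
        raise UsageError(f"unknown test {test!r}")
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    if np.isnan(p_value):  # identical constant groups
        p_value = 1.0
    return GroupComparison(
        group_names=(str(names[0]), str(names[1])),
        mean_eaa=(m1, m2),
        difference=m2 - m1,
        p_value=p_value,
        test_name=test_name,
        n=(len(g1), len(g2)),
        low_power=min(len(g1), len(g2)) < 5,
    )
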