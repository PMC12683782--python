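"""Synthetic methylation-aging cohorts for offline testing and validation.

The generator emulates the statistical structure the clock machinery
assumes, without attempting to mimic real array covariance or probe
chemistry: a subset of CpGs drift linearly with age (half hyper-, half
hypomethylating), Gaussian measurement noise is added, betas are clipped
to [0, 1], values go missing completely at random, and group-level age
acceleration is injected by shifting a sample's *effective* age before
betas are generated (its recorded chronological age stays unshifted, so a
good clock reads the shift out as EAA).

Because the generative model is known, :func:`generate_oracle_clock`
returns the linear clock that inverts it exactly on noiseless data —
the ground-truth baseline every downstream metric can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import MethylationMatrix, SampleMetadata
from .registry import ClockDefinition, Transform


class AgeDistribution(str, Enum):
    uniform_20_80 = "uniform_20_80"
    #: mid-heavy: 40-60y twice as dense as the flanking decades, mimicking
    #: donor cohorts dominated by middle-aged samples
    gtex_like_midheavy = "gtex_like_midheavy"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic aging cohort.

    ``n_age_cpgs`` CpGs carry a linear age signal (half positive slope,
    half negative); the rest are age-independent noise probes.
    ``noise_sd`` is in beta units; ``acceleration_by_group`` maps group
    labels to injected EAA in years (samples are assigned to groups
    uniformly at random).
    """

    n_samples: int = 200
    age_distribution: AgeDistribution = AgeDistribution.uniform_20_80
    n_cpgs: int = 50
    n_age_cpgs: int = 20
    noise_sd: float = 0.02
    missing_rate: float = 0.0
    acceleration_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_cpgs > self.n_cpgs:
            raise UsageError("n_age_cpgs cannot exceed n_cpgs")
        if self.n_age_cpgs < 1 or self.n_samples < 1:
            raise UsageError("need at least one sample and one age-CpG")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise UsageError("missing_rate must be in [0, 1)")
        if not isinstance(self.age_distribution, AgeDistribution):
            object.__setattr__(
                self,
                "age_distribution",
                AgeDistribution(self.age_distribution),
            )


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_samples
    if spec.age_distribution is AgeDistribution.uniform_20_80:
        return rng.uniform(20.0, 80.0, size=n)
    # mid-heavy mixture: 60% in 40-60, 20% each in 20-40 and 60-80
    comp = rng.choice(3, size=n, p=[0.2, 0.6, 0.2])
    lo = np.array([20.0, 40.0, 60.0])[comp]
    hi = np.array([40.0, 60.0, 80.0])[comp]
    return rng.uniform(lo, hi)


def _generative_params(
    spec: CohortSpec,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Baselines b0_j, slopes s_j and CpG ids (deterministic in seed).

    Slopes are in beta units per (age − 50)/100; age-CpGs get baselines
    near 0.5 so the linear signal rarely clips within 20-80y.
    """
    prng = np.random.default_rng(spec.seed + 1_000_003)
    cpg_ids = [f"cg{j:08d}" for j in range(1, spec.n_cpgs + 1)]
    b0 = prng.uniform(0.1, 0.9, size=spec.n_cpgs)
    s = np.zeros(spec.n_cpgs)
    n_pos = spec.n_age_cpgs - spec.n_age_cpgs // 2
    mags = prng.uniform(0.3, 0.8, size=spec.n_age_cpgs)
    signs = np.array([1.0] * n_pos + [-1.0] * (spec.n_age_cpgs // 2))
    s[: spec.n_age_cpgs] = signs * mags
    b0[: spec.n_age_cpgs] = prng.uniform(0.35, 0.65, size=spec.n_age_cpgs)
    return b0, s, cpg_ids


def generate_cohort(
    spec: CohortSpec,
) -> tuple[MethylationMatrix, SampleMetadata]:
    """Simulate a cohort: beta = clip(b0 + s·(age_eff − 50)/100 + ε, 0, 1).

    ``age_eff`` is chronological age plus the group's injected
    acceleration; ε ~ Normal(0, noise_sd²); missingness is MCAR at
    ``missing_rate``.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)
    groups = list(spec.acceleration_by_group)
    glabels = np.array(groups)[rng.integers(len(groups), size=spec.n_samples)]
    accel = np.array(
        [spec.acceleration_by_group[g] for g in glabels], dtype=float
    )
    b0, s, cpg_ids = _generative_params(spec)

    age_eff = ages + accel
    signal = b0[None, :] + s[None, :] * (age_eff[:, None] - 50.0) / 100.0
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
    betas = np.clip(signal + noise, 0.0, 1.0)
    if spec.missing_rate > 0:
        mask = rng.uniform(size=betas.shape) < spec.missing_rate
        betas = np.where(mask, np.nan, betas)

    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    matrix = MethylationMatrix(
        pd.DataFrame(betas, index=sample_ids, columns=cpg_ids)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"age": ages, "group": glabels},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, meta


def generate_oracle_clock(
    spec: CohortSpec, name: str = "Oracle"
) -> ClockDefinition:
    """The linear clock that inverts the generative model.

    Each age-CpG alone implies age = 50 + 100·(beta − b0_j)/s_j;
    averaging these estimates over the m age-CpGs gives weights
    w_j = 100/(m·s_j) and a matching intercept, so on noiseless,
    unclipped data predicted age equals true (effective) age exactly.
    """
    if spec.n_age_cpgs < 1:
        raise UsageError("spec has no age-linked CpGs; no oracle exists")
    b0, s, cpg_ids = _generative_params(spec)
    m = spec.n_age_cpgs
    idx = np.arange(m)
    w = 100.0 / (m * s[idx])
    intercept = 50.0 - float(np.sum(100.0 * b0[idx] / (m * s[idx])))
    return ClockDefinition(
        name=name,
        cpg_ids=tuple(cpg_ids[j] for j in idx),
        weights=w,
        intercept=intercept,
        transform=Transform.identity,
        platform="synthetic oracle (inverts the cohort generative model)",
    )


def generate_distractor_clock(
    spec: CohortSpec, seed: int, name: str = "Distractor"
) -> ClockDefinition:
    """A plausible-but-imperfect clock: the oracle with perturbed weights.

    Useful as a weak base model when testing the meta-learner; the
    perturbation adds both multiplicative weight noise and a bias.
    """
    oracle = generate_oracle_clock(spec, name=name)
    prng = np.random.default_rng(seed)
    w = oracle.weights * prng.uniform(0.6, 1.4, size=oracle.n_cpgs)
    intercept = oracle.intercept + prng.normal(0.0, 8.0)
    return ClockDefinition(
        name=name,
        cpg_ids=oracle.cpg_ids,
        weights=w,
        intercept=float(intercept),
        transform=Transform.identity,
        platform="synthetic distractor (perturbed oracle)",
    )
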