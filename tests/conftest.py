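import numpy as np
import pandas as pd
import pytest

import ensembleage as ea


@pytest.fixture
def clock_file(tmp_path):
    """Factory writing a minimal two-column clock CSV."""

    def _write(rows, name="toy.csv", header=True):
        path = tmp_path / name
        lines = ["CpG,Weight"] if header else []
        lines += [f"{cid},{w}" for cid, w in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def toy_clock():
    """Two-CpG identity clock: age = 10 + 100*b1 + 50*b2."""
    return ea.ClockDefinition(
        name="Toy",
        cpg_ids=("cg00000001", "cg00000002"),
        weights=np.array([100.0, 50.0]),
        intercept=10.0,
    )


@pytest.fixture
def small_matrix():
    """3 samples x 3 CpGs with one missing cell."""
    return ea.MethylationMatrix(
        pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.2, np.nan, 0.8], [0.3, 0.7, 0.7]],
            index=["A", "B", "C"],
            columns=["cg00000001", "cg00000002", "cg00000003"],
        )
    )


@pytest.fixture
def noiseless_cohort():
    """Noiseless synthetic cohort with its exact oracle clock."""
    spec = ea.CohortSpec(
        n_samples=120, n_cpgs=30, n_age_cpgs=10, noise_sd=0.0, seed=7
    )
    matrix, meta = ea.generate_cohort(spec)
    return spec, matrix, meta, ea.generate_oracle_clock(spec)


def random_clockset(rng, n_clocks=5, n_cpgs=20, universe=50):
    """Random clocks drawing CpGs from a small shared universe."""
    ids = [f"cg{j:08d}" for j in range(1, universe + 1)]
    clocks = []
    for i in range(n_clocks):
        chosen = rng.choice(universe, size=n_cpgs, replace=False)
        clocks.append(
            ea.ClockDefinition(
                name=f"C{i}",
                cpg_ids=tuple(ids[j] for j in chosen),
                weights=rng.normal(size=n_cpgs),
                intercept=float(rng.normal()),
            )
        )
    return clocks
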