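import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tmbpanel import MutationMatrix, SimParams, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(counts: dict[str, dict[str, int]], samples: list[str]) -> MutationMatrix:
    """Build a small MutationMatrix from {gene: {sample: count}}."""
    genes = sorted(counts)
    df = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    for g, per_sample in counts.items():
        for s, c in per_sample.items():
            df.at[g, s] = c
    return MutationMatrix(counts=df)


def random_matrix(rng: np.random.Generator, n_genes: int = 20, n_samples: int = 10) -> MutationMatrix:
    """Random small count matrix for identity/property checks."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    counts = rng.poisson(1.0, size=(n_genes, n_samples)).astype(np.int64)
    return MutationMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    params = SimParams(n_samples=150, n_genes=400, n_informative=40, seed=5)
    matrix, clinical, truth = simulate_cohort(params)
    return matrix, clinical, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's standard study conditions (n=500, 2000 genes, 150 informative)."""
    matrix, clinical, truth = simulate_cohort(SimParams(seed=20))
    return matrix, clinical, truth
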