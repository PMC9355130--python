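import numpy as np
import pytest

from genofirst import simulate
from genofirst.config import CohortConfig
from genofirst.domain import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_participants=2000, seed=11, n_x_variants=8)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture()
def toy_matrix() -> GenotypeMatrix:
    """4 variants x 30 samples; v1 has poor call rate, v2 is all-het on X."""
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 2, size=(4, 30)).astype(np.int8)
    geno[1, :18] = -1  # call rate 0.4
    geno[2, :] = 1  # all-het: extreme HWE violation
    return GenotypeMatrix(
        source="array",
        variant_ids=["v0", "v1", "v2", "v3"],
        chroms=["1", "2", "X", "7"],
        sample_ids=[f"S{i}" for i in range(30)],
        genotypes=geno,
    )
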