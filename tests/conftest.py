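import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vdpower import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

ALLELES = ("A", "C", "G", "T")


def random_matrix(seed, m=8, n_loci=5, n_alleles=4, missing_rate=0.0, marker_type="SNP"):
    """Random diploid genotype matrix for property tests."""
    rng = np.random.default_rng(seed)
    alleles = ALLELES[:n_alleles]
    grid = np.empty((m, n_loci), dtype=object)
    for i in range(m):
        for j in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                grid[i, j] = None
            else:
                a, b = rng.choice(alleles, size=2)
                grid[i, j] = f"{a}/{b}"
    return GenotypeMatrix.from_calls(grid, marker_type=marker_type)


@pytest.fixture
def matrix_factory():
    return random_matrix


@pytest.fixture
def ten_locus_pair():
    """Two samples differing at exactly loci L1, L5, L9 of ten."""
    base = ["A/A", "C/C", "G/G", "T/T", "A/C", "A/G", "A/T", "C/G", "C/T", "G/T"]
    other = list(base)
    other[0] = "A/T"   # L1
    other[4] = "C/C"   # L5
    other[8] = "G/G"   # L9
    return GenotypeMatrix.from_calls([base, other], sample_ids=["s1", "s2"])
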