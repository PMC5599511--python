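import numpy as np
import pytest

from gmaptad.hic_io import ContactMatrix, Domain, DomainSet
from gmaptad.simulate import SimConfig, simulate_hic


@pytest.fixture(scope="session")
def default_truth():
    """One TAD-only simulated matrix under the study's default conditions."""
    return simulate_hic(SimConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm(rng):
    """A small symmetric contact matrix with a dense 10-bin block."""
    n = 40
    v = rng.poisson(2.0, size=(n, n)).astype(float)
    v[10:20, 10:20] += rng.poisson(20.0, size=(10, 10))
    v = np.triu(v, 1)
    v = v + v.T
    return ContactMatrix(v, resolution_bp=40_000, chrom="chrT")


@pytest.fixture
def two_level_domainset():
    tad1 = Domain(10, 30, level=0)
    tad2 = Domain(30, 50, level=0)
    sub = Domain(12, 20, level=1, parent=tad1)
    return DomainSet([tad1, tad2, sub], chrom="chr1", resolution_bp=40_000,
                     n_bins=60)
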