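import numpy as np
import pytest

from sweepis.haplotype_coding import (
    CodedHaplotype,
    RecombinationMap,
    SampleConfiguration,
    SelectedHaplotypeMatrix,
)
from sweepis.wf_trajectory import Demography, SelectionModel, sample_trajectory


@pytest.fixture(scope="session")
def uniform_map_25():
    """25 SNPs, 1 cM/Mb over 24 kb steps (uniform in genetic distance)."""
    return RecombinationMap.uniform(np.arange(1, 26) * 24_000, 1.0)


@pytest.fixture(scope="session")
def g6pd_map():
    """25 uniformly spaced markers across 440 kb at 1.4410 cM/Mb."""
    positions = np.round(np.linspace(0, 440_000, 25)).astype(np.int64)
    return RecombinationMap.uniform(positions, 1.4410)


@pytest.fixture(scope="session")
def g6pd_config():
    """The published 10-haplotype sample configuration of the G6PD data."""
    return SampleConfiguration(
        [CodedHaplotype(11, 7), CodedHaplotype(4, 7),
         CodedHaplotype(12, 7), CodedHaplotype(17, 7)],
        [5, 1, 1, 3],
    )


def _rows_for(code, n, m=25, mutant=17):
    rows, masks = [], []
    allele = np.zeros(m, dtype=np.int8)
    mask = np.zeros(m, dtype=bool)
    lo, hi = mutant - code.r1, mutant + code.r2
    mask[lo:hi + 1] = True
    allele[lo:hi + 1] = 1
    for p in code.muts:
        allele[p] = 0
    return [allele.copy() for _ in range(n)], [mask.copy() for _ in range(n)]


@pytest.fixture(scope="session")
def coded_example_matrix():
    """10 selected haplotypes over 25 SNPs collapsing to four coded groups,
    with the selected site at column 18 (1-based); includes the codes
    (7, 6) and (12, 7) + mutation at position 21."""
    groups = [
        (CodedHaplotype(7, 6), 4),
        (CodedHaplotype(12, 7, (20,)), 1),   # 1-based position 21
        (CodedHaplotype(17, 7), 3),
        (CodedHaplotype(11, 2), 2),
    ]
    rows, masks = [], []
    for code, n in groups:
        r, mk = _rows_for(code, n)
        rows += r
        masks += mk
    return SelectedHaplotypeMatrix(
        np.array(rows), 17, np.array(masks), np.arange(1, 26) * 24_000,
        ancestral_alleles=np.ones(25, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_trajectory():
    """Fixed-seed sweep trajectory at 2N = 200, s = 0.1, x0 = 0.6."""
    rng = np.random.default_rng(3)
    traj = sample_trajectory(120, SelectionModel.additive(0.1),
                             Demography(N0=100), rng)
    assert traj is not None
    return traj


@pytest.fixture(scope="session")
def tiny_trajectory():
    """Very small population (2N = 60) for exact comparisons."""
    rng = np.random.default_rng(4)
    traj = sample_trajectory(36, SelectionModel.additive(0.2),
                             Demography(N0=30), rng)
    assert traj is not None
    return traj
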