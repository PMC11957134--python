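import numpy as np
import pytest

import clonescope as cs


@pytest.fixture(scope="session")
def benchmark_truth():
    """One 16-cell / 8-group serial-expansion simulation shared across tests."""
    truth, genotypes = cs.simulate_clone_tree(
        **cs.invitro_benchmark_design(), mutations_per_day=4.0, seed=11)
    return truth, genotypes


@pytest.fixture(scope="session")
def het_snps():
    return cs.simulate_het_snp_positions(3000, chrom="chr13", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
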