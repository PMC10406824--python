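import numpy as np
import pandas as pd
import pytest

from tmontanum.data_io import GenotypeTable, load_fixtures
from tmontanum.synthetic_data import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture()
def tiny_genotypes():
    """Three populations, two loci, fully typed; hand-checkable frequencies."""
    rows = []
    # P1: locus L1 alleles 100/102 mixed, L2 monomorphic
    for i, (a, b) in enumerate([(100, 100), (100, 102), (102, 102), (100, 102)]):
        rows.append(("P1", f"P1_{i}", "L1", a, b))
        rows.append(("P1", f"P1_{i}", "L2", 200, 200))
    # P2: L1 fixed for 104 (private), L2 monomorphic same allele as P1
    for i in range(3):
        rows.append(("P2", f"P2_{i}", "L1", 104, 104))
        rows.append(("P2", f"P2_{i}", "L2", 200, 200))
    # P3: all heterozygous at L1, shares alleles with P1
    for i in range(3):
        rows.append(("P3", f"P3_{i}", "L1", 100, 102))
        rows.append(("P3", f"P3_{i}", "L2", 200, 200))
    return GenotypeTable(pd.DataFrame(
        rows, columns=["population", "individual", "locus", "allele_a", "allele_b"]))


@pytest.fixture(scope="session")
def large_genotypes():
    """One deep population per inbreeding level, for estimator recovery."""
    out = {}
    for f in (0.0, 0.1, 0.2):
        config = SimConfig(n_populations=1, n_individuals=500, n_loci=9,
                           n_alleles=8, he_target=0.65, inbreeding_f=f,
                           missing_rate=0.0)
        out[f] = simulate_genotypes(config, seed=12345 + int(f * 100))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20160605)
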