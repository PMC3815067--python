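import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

from lofgwas.genodata import MISSING, GenotypeMatrix, PhenotypeTable


def make_genotypes(calls, chroms=None, positions=None, sample_ids=None):
    """Build a small GenotypeMatrix from a call array with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chroms is None:
        chroms = ["1"] * m
    if positions is None:
        positions = list(range(100, 100 + 10 * m, 10))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    ids = [f"S{c}_{p}" for c, p in zip(chroms, positions)]
    return GenotypeMatrix(
        sample_ids=np.asarray(sample_ids, dtype=object),
        snp_ids=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms, dtype=object),
        position=np.asarray(positions, dtype=np.int64),
        calls=calls,
        allele1=np.asarray(["A"] * m, dtype=object),
        allele2=np.asarray(["C"] * m, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_panel(rng):
    """60 inbred samples x 30 random SNPs with a binary trait."""
    calls = (2 * (rng.random((60, 30)) < rng.uniform(0.1, 0.9, 30))).astype(np.int8)
    g = make_genotypes(calls)
    trait = rng.integers(0, 2, 60).astype(np.int8)
    p = PhenotypeTable(g.sample_ids.copy(), trait)
    return g, p
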