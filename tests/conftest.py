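import numpy as np
import pandas as pd
import pytest

from boronmap.containers import MISSING, GenotypeMatrix


def make_genotype_matrix(calls, positions=None, chrom="chr1",
                         dp=30, gq=99, samples=None):
    """Small GenotypeMatrix from an explicit call matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, p = calls.shape
    if samples is None:
        samples = [f"S{i:04d}" for i in range(n)]
    if positions is None:
        positions = np.arange(1, p + 1) * 100
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=int),
        "ref": ["A"] * p,
        "alt": ["T"] * p,
    })
    variants["id"] = [f"{chrom}:{q}" for q in variants["pos"]]
    dp_arr = np.full(calls.shape, dp, dtype=np.int32) \
        if np.isscalar(dp) else np.asarray(dp, dtype=np.int32)
    gq_arr = np.full(calls.shape, gq, dtype=np.int32) \
        if np.isscalar(gq) else np.asarray(gq, dtype=np.int32)
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls,
                          dp=dp_arr, gq=gq_arr)


@pytest.fixture
def tiny_genotypes():
    """Eight inbred lines, six variants, no missing data."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(8, 6)).astype(np.int8)
    # make sure every variant segregates
    calls[0] = 0
    calls[1] = 1
    return make_genotype_matrix(calls)


@pytest.fixture
def ionome_table():
    """Balanced complete 6-accession x 3-block design with known effects."""
    rng = np.random.default_rng(7)
    rows = []
    genetic = {f"A{i}": 30.0 + 2.0 * i for i in range(6)}
    blocks = {"block1": -1.5, "block2": 0.0, "block3": 1.5}
    for acc, gv in genetic.items():
        for blk, bv in blocks.items():
            rows.append([f"{acc}_{blk}", acc, blk, 1,
                         gv + bv + rng.normal(0, 0.5),
                         abs(rng.normal(0.5, 0.1)),
                         abs(rng.normal(2.0, 0.4))])
    return pd.DataFrame(rows, columns=["sample_id", "accession", "block",
                                       "replicate", "B", "Cr", "Ti"])
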