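import numpy as np
import pandas as pd
import pytest

from spudsel import simulate
from spudsel.matrices import DosageMatrix, ReadCountMatrix


@pytest.fixture(scope="session")
def small_truth():
    """A 30-cultivar, 60-locus cohort with default LD structure."""
    return simulate.simulate_cohort(30, 60, seed=7)


@pytest.fixture(scope="session")
def high_ld_truth():
    """Whole-chromosome 2-founder blocks: near-perfect within-block LD."""
    return simulate.simulate_cohort(
        60, 40, seed=3, n_founders=2, ld_block_bp=100_000_000
    )


def make_loci(n, chrom="chr01", start=1000, step=1000):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": [start + i * step for i in range(n)],
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )


def make_dosage(codes, samples=None, continuous=False):
    codes = np.asarray(codes, dtype=float)
    samples = samples or [f"s{i}" for i in range(codes.shape[0])]
    return DosageMatrix(
        samples=list(samples),
        loci=make_loci(codes.shape[1]),
        codes=codes,
        continuous=continuous,
    )


def make_counts(ref, alt, samples=None):
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    samples = samples or [f"s{i}" for i in range(ref.shape[0])]
    return ReadCountMatrix(
        samples=list(samples),
        loci=make_loci(ref.shape[1]),
        ref_depth=ref,
        alt_depth=alt,
    )
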