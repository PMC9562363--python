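"""Shared fixtures: small simulated samples reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cfdeconv.genetics import Hypothesis
from cfdeconv.simulate import Scenario, simulate_sample


@pytest.fixture(scope="session")
def euploid_sample():
    """A mid-size euploid sample (FF 0.10, depth 800)."""
    sc = Scenario(
        fetal_fraction=0.10,
        mean_depth=800,
        n_target_snps=300,
        n_reference_snps=500,
        seed=11,
    )
    return simulate_sample(sc)


@pytest.fixture(scope="session")
def mii_trisomy_sample():
    """An MII trisomy 21 sample (FF 0.10, depth 800)."""
    sc = Scenario(
        ploidy_hypothesis=Hypothesis.MII,
        fetal_fraction=0.10,
        mean_depth=800,
        n_target_snps=300,
        n_reference_snps=500,
        seed=12,
    )
    return simulate_sample(sc)


def snp_table(af, depth=1000, p=0.5, chrom="chr21"):
    """Hand-built SNP table with exact allele fractions."""
    af = np.atleast_1d(np.asarray(af, dtype=float))
    n_alt = np.rint(af * depth).astype(int)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(len(af)) + 1) * 1000,
            "p": p,
            "n_alt": n_alt,
            "n_ref": depth - n_alt,
            "depth": depth,
        }
    )
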