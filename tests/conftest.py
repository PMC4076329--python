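"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from transfinemap.geno_io import GenotypeMatrix, PhenotypeTable, VariantRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(calls, snp_ids=None, alleles=("G", "A")):
    """GenotypeMatrix from an (n_samples x n_snps) int array (-1 missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    ids = snp_ids or [f"snp{j + 1}" for j in range(m)]
    variants = [
        VariantRecord(ids[j], "16", 1000 + 100 * j, alleles[0], alleles[1], alleles[1])
        for j in range(m)
    ]
    samples = [f"s{i + 1}" for i in range(calls.shape[0])]
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


def make_pheno(samples, bmi=None, t2d=None, sex=None, age=None, population="pop"):
    n = len(samples)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": sex if sex is not None else np.ones(n, dtype=int),
            "age": age if age is not None else np.full(n, 50.0),
            "bmi": bmi if bmi is not None else np.full(n, np.nan),
            "t2d": t2d if t2d is not None else ["unknown"] * n,
            "population": population,
            "panel": population,
        }
    )
    return PhenotypeTable(df)
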