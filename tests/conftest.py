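import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ibdkit import AnalysisConfig, GenotypeTable
from ibdkit.simulate import SimOptions, standard_pedigrees

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def peds():
    return standard_pedigrees()


@pytest.fixture(scope="session")
def fast_opts() -> SimOptions:
    """Reduced marker density for structural tests that do not need
    fine window granularity."""
    return SimOptions(n_markers=40_000)


def make_table(calls, chrom=None, pos=None, ids=None) -> GenotypeTable:
    """Build a small GenotypeTable from a call matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = np.asarray(chrom if chrom is not None else np.ones(m), dtype=np.int16)
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000,
                     dtype=np.int64)
    ids = ids or [f"s{i}" for i in range(n)]
    samples = pd.DataFrame({
        "iid": ids, "fid": ["F"] * n, "father": ["0"] * n,
        "mother": ["0"] * n, "sex": ["0"] * n, "phenotype": ["-9"] * n})
    markers = pd.DataFrame({
        "chrom": chrom, "id": [f"m{j}" for j in range(m)],
        "cm": pos / 1e6, "pos": pos})
    return GenotypeTable(samples=samples, markers=markers, calls=calls)
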