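import numpy as np
import pandas as pd
import pytest

from tpghallmarks.models import ContactMatrix, GeneModel
from tpghallmarks.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=300, n_bins=100, n_transloc=80)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One modest synthetic bundle shared by read-only tests."""
    return simulate_bundle(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_genes():
    return {
        "GA": GeneModel("GA", "chr1", "+", 10_000, 16_000, 100,
                        utr3_start=15_000, utr3_end=16_000),
        "GB": GeneModel("GB", "chr1", "-", 40_000, 50_000, 200,
                        utr3_start=40_000, utr3_end=41_500),
        "GC": GeneModel("GC", "chr2", "+", 5_000, 12_000, 150),
    }


def make_matrix(n_chrom=2, bins_per_chrom=3, bin_size=10_000, fill=0.0):
    rows = []
    for c in range(n_chrom):
        for b in range(bins_per_chrom):
            rows.append({"bin_id": len(rows), "chrom": f"chr{c + 1}",
                         "start": b * bin_size, "end": (b + 1) * bin_size})
    n = n_chrom * bins_per_chrom
    return ContactMatrix(pd.DataFrame(rows), np.full((n, n), float(fill)))


@pytest.fixture()
def uniform_matrix():
    return make_matrix(n_chrom=2, bins_per_chrom=3, fill=5.0)
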