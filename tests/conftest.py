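import numpy as np
import pandas as pd
import pytest

from pathsel import (
    GenotypeStudy,
    HaplotypePanel,
    SimulationSpec,
    VariantInfo,
    simulate_neutral_panel,
)


def make_variants(n, chrom="1", spacing=1000, cm_per_mb=1.0):
    return [
        VariantInfo(
            id=f"v{j}", chrom=chrom, pos_bp=(j + 1) * spacing,
            ancestral="ref", map_cM=(j + 1) * spacing * cm_per_mb * 1e-6,
        )
        for j in range(n)
    ]


def make_panel(H, chrom="1", spacing=1000):
    H = np.asarray(H, dtype=np.int8)
    samples = [f"s{i}" for i in range(H.shape[0] // 2)]
    return HaplotypePanel(make_variants(H.shape[1], chrom, spacing), H, samples)


def make_study(G, y=None, age=None, seed=0):
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    if y is None:
        y = rng.integers(0, 2, n)
    if age is None:
        age = rng.normal(60.0, 8.0, n)
    samples = [f"s{i}" for i in range(n)]
    cov = pd.DataFrame({"age": np.asarray(age, dtype=float)}, index=samples)
    return GenotypeStudy(make_variants(G.shape[1]), G, samples, np.asarray(y), cov)


def random_null_study(n, m, seed, maf_low=0.1, maf_high=0.5):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, m)
    G = rng.binomial(2, freqs, size=(n, m)).astype(float)
    return make_study(G, seed=seed + 1)


@pytest.fixture(scope="session")
def neutral_panel_2000():
    """The neutral study-scale panel used by the calibration checks."""
    return simulate_neutral_panel(SimulationSpec(rng_seed=11))


@pytest.fixture
def small_spec():
    return SimulationSpec(n_haplotypes=200, n_snps=120, rng_seed=3)
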