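import numpy as np
import pandas as pd
import pytest

from epidiverge.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """2-Mb, 5-vs-5 cohort with planted DMRs, couplings and divergence."""
    return SimConfig(genome_spec={"chr1": 2_000_000}, seed=3,
                     n_planted_dmrs={"CG": 20, "CHG": 10, "CHH": 20},
                     n_snps=4000, n_divergent_windows=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Minimal cohort for I/O round-trips and determinism checks."""
    return SimConfig(genome_spec={"chr1": 300_000}, seed=9,
                     n_genes=20, n_tes=10,
                     n_planted_dmrs={"CG": 4, "CHG": 0, "CHH": 4},
                     n_coupled_genes={"CG": 3, "CHG": 0, "CHH": 3},
                     n_snps=300, n_divergent_windows=1, window_bp=50_000,
                     control_length_bp=30_000)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def toy_sites() -> pd.DataFrame:
    """Hand-built cytosine table factory helpers use directly."""
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(10_000, size=400, replace=False))
    depth = rng.poisson(20, size=400) + 1
    meth = rng.binomial(depth, 0.5)
    return pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "strand": np.where(rng.random(400) < 0.5, "+", "-"),
        "context": rng.choice(["CG", "CHG", "CHH"], size=400),
        "depth": depth, "meth": meth})
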