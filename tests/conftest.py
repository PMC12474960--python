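import numpy as np
import pandas as pd
import pytest

from jucara import simulate


@pytest.fixture(scope="session")
def biometric_20x5():
    """Balanced 20-genotype × 5-replicate dataset with known components."""
    cfg = simulate.SimulationConfig(
        n_genotypes=20, n_reps=5, sigma2_g=2.0, sigma2_e=1.0, seed=42
    )
    table, truth = simulate.simulate_biometric(cfg)
    return table, truth


@pytest.fixture(scope="session")
def ssr_panel():
    """59-genotype SSR panel at 8 loci, no inbreeding."""
    cfg = simulate.SimulationConfig(seed=7)
    table, truth = simulate.simulate_ssr(cfg)
    return table, truth


@pytest.fixture
def two_trait_long():
    """Long table with two genetically correlated traits on shared units."""
    rng = np.random.default_rng(11)
    i, r = 40, 4
    G0 = np.array([[1.0, 0.9], [0.9, 1.0]])
    g = rng.multivariate_normal([0, 0], G0, size=i)
    e = rng.normal(size=(i, r, 2))
    y = 5.0 + g[:, None, :] + e
    rows = []
    for gi in range(i):
        for rj in range(r):
            rows.append((f"G{gi + 1:03d}", rj + 1, "t1", y[gi, rj, 0]))
            rows.append((f"G{gi + 1:03d}", rj + 1, "t2", y[gi, rj, 1]))
    return pd.DataFrame(rows, columns=["genotype", "replicate", "trait", "value"])
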