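"""Shared fixtures: all data is generated programmatically at test time."""
import numpy as np
import pandas as pd
import pytest

from landgen.genio import GenotypeMatrix
from landgen.simulate import LandscapeConfig, simulate_genotypes, simulate_landscape


def small_config(**overrides) -> LandscapeConfig:
    defaults = dict(n_neutral=300, n_highfst=15, n_clim=20, fst_elevated=0.25,
                    clim_effect=1.5, seed=11)
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


@pytest.fixture(scope="session")
def fixture_system():
    """One small simulated system shared across tests (read-only)."""
    cfg = small_config()
    grid, sites = simulate_landscape(cfg)
    matrix = simulate_genotypes(sites, cfg)
    return cfg, grid, sites, matrix


def toy_matrix(genotypes, pops=None, depth=None, positions=None):
    """Hand-built GenotypeMatrix from a small integer array."""
    G = np.asarray(genotypes, dtype=np.int16)
    n, m = G.shape
    pops = pops or ["A"] * n
    loci = pd.DataFrame(
        {
            "contig": ["c1"] * m,
            "pos": positions if positions is not None else list(range(1, m + 1)),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "diallelic": [True] * m,
        }
    )
    return GenotypeMatrix(G, [f"i{j}" for j in range(n)], pops, loci, depth=depth)
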