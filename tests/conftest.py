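"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

import gpeval as gp


@pytest.fixture(scope="session")
def small_panel():
    """Unstructured panel, 120 individuals x 300 SNPs on two chromosomes."""
    layout = gp.random_layout([("chr1", 2_000_000), ("chr2", 1_000_000)], 300, seed=11)
    return gp.simulate_genotypes(120, layout, ld_decay=0.0, seed=12)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    """Moderately heritable polygenic trait on the small panel."""
    return gp.simulate_phenotypes(
        small_panel, gp.TraitArchitecture(n_qtl=30, h2=0.5, seed=13)
    )


@pytest.fixture(scope="session")
def toy_split(small_panel, small_trait):
    """Deterministic 80/20 train/validation index split of the small panel."""
    rng = np.random.default_rng(14)
    perm = rng.permutation(small_panel.n)
    n_val = small_panel.n // 5
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])
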