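"""Shared fixtures: hand-built tiny matrices and module-scoped simulations.

Simulations are expensive enough to share; tests must not mutate fixture
matrices (use .copy() when planting)."""

import numpy as np
import pandas as pd
import pytest

import cottonpop as cp


def tiny_panel(n_h=4, n_b=4, n_out=1):
    rows = []
    rows += [(f"H{i}", "hirsutum", "race" if i % 2 else "cultivar", "")
             for i in range(n_h)]
    rows += [(f"B{i}", "barbadense", "cultivar", "") for i in range(n_b)]
    rows += [(f"O{i}", "outgroup", "outgroup", "") for i in range(n_out)]
    return cp.AccessionPanel(pd.DataFrame(rows, columns=["id", "species",
                                                         "group", "origin"]))


def matrix_from_calls(calls, panel=None, chrom="A01", spacing=100):
    """Build a GenotypeMatrix from a raw calls array (acc x site)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_sites = calls.shape
    if panel is None:
        rows = [(f"S{i}", "hirsutum", "race", "") for i in range(n_acc)]
        panel = cp.AccessionPanel(pd.DataFrame(
            rows, columns=["id", "species", "group", "origin"]))
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": np.arange(1, n_sites + 1) * spacing,
        "ref": ["A"] * n_sites, "alt": ["T"] * n_sites,
        "vtype": ["snp"] * n_sites})
    return cp.GenotypeMatrix(panel, sites, calls)


def random_matrix(rng, n_acc=12, n_sites=60, missing=0.1, panel=None,
                  chrom="A01"):
    calls = rng.integers(0, 3, (n_acc, n_sites)).astype(np.int8)
    calls[rng.random(calls.shape) < missing] = cp.MISSING
    return matrix_from_calls(calls, panel=panel, chrom=chrom)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across the session."""
    return cp.simulate_genotypes(cp.SimConfig(seed=101))


@pytest.fixture(scope="session")
def default_filtered(default_sim):
    return cp.filter_cascade(default_sim.matrix, seed=101)


@pytest.fixture(scope="session")
def small_sim_config():
    """Fast, low-density configuration for Monte-Carlo loops where the
    absolute diversity scale is irrelevant."""
    def make(seed, **overrides):
        kw = dict(snp_density=2.0, n_race=12, n_cultivar=16,
                  n_barbadense=16, n_outgroup=4, seed=seed)
        kw.update(overrides)
        return cp.SimConfig(**kw)
    return make


@pytest.fixture(scope="session")
def gene_sim():
    return cp.simulate_gene_models(cp.default_layout(), n_genes=40, seed=5)
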