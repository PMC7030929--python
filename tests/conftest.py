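"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from glyconet import loci as lm
from glyconet import simulate as sim
from glyconet import sumstats as ss


@pytest.fixture(scope="session")
def small_sim():
    """Zero-noise 9-locus / 3-cluster dataset with meta-analysis results."""
    cfg = sim.SimulationConfig(
        n_loci=9,
        n_clusters=3,
        background_pool_size=300,
        noise_sd=0.0,
        seed=11,
    )
    sumstats, truth = sim.simulate_multicohort_gwas(cfg)
    sumstats, truth = sim.derive_normalized_traits(sumstats, truth, seed=12)
    meta = ss.meta_analyze(sumstats)
    return {"config": cfg, "sumstats": sumstats, "truth": truth, "meta": meta}


@pytest.fixture(scope="session")
def called_loci(small_sim):
    calls = lm.classify_associations(small_sim["meta"])
    ld = lm.LDSource(small_sim["truth"].ld_r2)
    found = lm.define_loci(calls, ld, warn=False)
    return {"calls": calls, "loci": found, "ld": ld}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
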