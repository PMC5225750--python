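import numpy as np
import pandas as pd
import pytest

import clonegs as cg


@pytest.fixture(scope="session")
def sim_single():
    """One clonally replicated trial with moderate heritability (shared)."""
    cfg = cg.SimConfig(n_parents=20, progeny_per_cross=10, n_markers=600,
                       n_lgs=6, n_qtl=60, h2=0.38, seed=11)
    return cg.simulate_trials(cfg)


@pytest.fixture(scope="session")
def sim_single_qc(sim_single):
    markers, _ = cg.qc_filter(sim_single.trial_markers())
    return markers


@pytest.fixture(scope="session")
def sim_single_grm(sim_single_qc):
    return cg.bend_psd(cg.grm_yang(sim_single_qc, complete_case=False))


@pytest.fixture(scope="session")
def sim_pair():
    """Two connected trials with Type-B additive correlation 0.75."""
    cfg = cg.SimConfig(n_parents=16, progeny_per_cross=10, n_markers=500,
                       n_lgs=5, n_qtl=50, h2=0.35, type_b=0.75, seed=11)
    return cg.simulate_trials(cfg, trials=("T1", "T2"))


def random_marker_matrix(rng, n, p, freq_range=(0.1, 0.9), miss_frac=0.0):
    freqs = rng.uniform(*freq_range, size=p)
    X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    if miss_frac > 0:
        mask = rng.random((n, p)) < miss_frac
        X[mask] = np.nan
    return cg.MarkerMatrix([f"i{i}" for i in range(n)],
                           [f"m{j}" for j in range(p)], X)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
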