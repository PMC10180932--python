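"""Shared fixtures: small deterministic trajectories and the heavyweight
session-scope simulation runs used by the statistical and acceptance tests.

Problem sizes: the shear sweep uses 1.2e7 stride-10 production steps per
shear rate for the mode statistics plus 20 contiguous stride-1 segments
of 5e5 steps for the rotation estimator (whose noise is white per sampled
step), and the zero-shear reference run 1.6e7 steps, sized so that the
slowest mode rate (Gamma_1 ~ 0.04) is determined to a few percent (the
Fisher bound for an Ornstein-Uhlenbeck rate observed over total time T is
sqrt(2/(Gamma*T)) relative).  All seeds are fixed.
"""

import numpy as np
import pytest

import shearchain as sc

SWEEP_G = [0.0, 0.025, 0.05, 0.075, 0.1, 0.125, 0.15]


@pytest.fixture(scope="session")
def base_config():
    return sc.SimulationConfig(n_beads=16, n_production_steps=12_000_000,
                               n_thermalization_steps=1_000_000, seed=0)


@pytest.fixture(scope="session")
def sweep_summary(base_config):
    """Full shear sweep G in [0, 0.15]; the workhorse of the sheared-chain tests."""
    return sc.run_sweep(base_config, SWEEP_G, rotation_segment_steps=500_000)


@pytest.fixture(scope="session")
def zero_shear_run():
    """Long unsheared run for rate recovery, COM diffusion and mode statistics."""
    cfg = sc.SimulationConfig(n_beads=16, n_production_steps=16_000_000,
                              n_thermalization_steps=400_000, seed=42)
    return sc.simulate(cfg)


@pytest.fixture(scope="session")
def run_g003():
    """Moderate-shear run (G = 0.03) for the wavelet mobility ordering."""
    cfg = sc.SimulationConfig(n_beads=16, shear_rate=0.03,
                              n_production_steps=2_000_000,
                              n_thermalization_steps=400_000, seed=7)
    return sc.simulate(cfg)


@pytest.fixture
def short_run():
    """Small but statistically meaningful equilibrium run (N=8, G=0)."""
    cfg = sc.SimulationConfig(n_beads=8, n_production_steps=400_000,
                              n_thermalization_steps=50_000, seed=5)
    return sc.simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
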