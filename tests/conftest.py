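"""Shared fixtures: a small synthetic study and cached quadrature grids."""

import numpy as np
import pytest

from homeopop import prf, simulate


@pytest.fixture(scope="session")
def quad18():
    return prf.DFEQuadrature(18)


@pytest.fixture(scope="session")
def quad25():
    return prf.DFEQuadrature(25)


@pytest.fixture(scope="session")
def small_study():
    """A 12-gene study with clean records (no injected violations)."""
    cfg = simulate.SimulationConfig(seed=42, n_genes=12, gene_length_bp=600)
    return simulate.simulate_study(cfg)


@pytest.fixture(scope="session")
def dirty_study():
    """A study with injected filter violations and heterozygotes."""
    cfg = simulate.SimulationConfig(
        seed=43, n_genes=10, gene_length_bp=600, het_rate=0.05,
        qd_violation_rate=0.10, mq_violation_rate=0.06,
        mqranksum_violation_rate=0.06, gq_violation_rate=0.05,
        dp_violation_rate=0.05, excess_dp_rate=0.05)
    return simulate.simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
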