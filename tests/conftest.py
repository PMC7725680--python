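"""Shared fixtures.

Full-size network runs (N = 10^4, the reference parameter set) are
expensive, so they are session-scoped and shared between the statistics
and acceptance tests.  Simulated analysis windows are kept at a few
seconds; the quantities asserted on them (rates, voltage moments, CV,
spectra, avalanche exponents) equilibrate well within that.
"""

import numpy as np
import pytest

from eicrit import NetworkConfig, build_connectivity, simulate_network
from eicrit import meanfield as mf
from eicrit.fixtures import generate_poisson_raster

FULL_N = 10_000
DURATION = 4000.0       # ms, incl. 1000 ms discarded transient
CONN_SEED = 42
SIM_SEED = 7


def scaled_config(N: int, **kw) -> NetworkConfig:
    """Reduced-size configuration with synaptic weights rescaled by
    sqrt(10^4 / N) to preserve the O(1/sqrt(N)) balanced scaling."""
    f = np.sqrt(10_000 / N)
    weights = dict(J_EO=0.45 * f, J_IO=0.72 * f, J_EE=0.36 * f,
                   J_IE=0.72 * f, J_EI=-0.81 * f, J_II=-1.44 * f)
    weights.update(kw)
    return NetworkConfig(N=N, **weights)


@pytest.fixture(scope="session")
def full_conn():
    cfg = NetworkConfig(N=FULL_N)
    return build_connectivity(cfg, CONN_SEED)


def _run(full_conn, tau_d_I, Q_o=5.0, duration=DURATION):
    cfg = NetworkConfig(N=FULL_N, duration=duration, discard=1000.0,
                        tau_d_I=tau_d_I, Q_o=Q_o, seed=CONN_SEED)
    raster, trace = simulate_network(cfg, full_conn, seed=SIM_SEED)
    return cfg, raster, trace


@pytest.fixture(scope="session")
def async_run(full_conn):
    """Fast-inhibition (tau_d_I = 1 ms) asynchronous reference state."""
    return _run(full_conn, 1.0)


@pytest.fixture(scope="session")
def sigma_calibration(async_run):
    cfg, raster, trace = async_run
    return mf.calibrate_sigma_from_run(raster, trace, cfg)


@pytest.fixture(scope="session")
def hopf_result(sigma_calibration):
    sE, sI = sigma_calibration
    params = mf.FieldParams.from_network_config(NetworkConfig(N=FULL_N), sE, sI)
    return mf.hopf_scan(params, np.arange(1.0, 4.51, 0.05))


@pytest.fixture(scope="session")
def critical_run(full_conn, hopf_result):
    """Network at the field-predicted Hopf point (the critical state)."""
    assert hopf_result.bifurcation_found
    return _run(full_conn, float(hopf_result.tau_dI_critical))


@pytest.fixture(scope="session")
def sync_run(full_conn):
    """Slow-inhibition (tau_d_I = 3.5 ms) sparsely synchronous state."""
    return _run(full_conn, 3.5)


@pytest.fixture(scope="session")
def super_run(full_conn):
    """Supercritical (tau_d_I = 4.3 ms) collective-oscillation state."""
    return _run(full_conn, 4.3)


@pytest.fixture(scope="session")
def critical_qo_runs(full_conn, hopf_result, critical_run):
    """Critical-state runs across external input strengths Q_o (Hz)."""
    td = float(hopf_result.tau_dI_critical)
    runs = {5.0: critical_run}
    for qo in (4.0, 6.0, 7.0, 8.0):
        runs[qo] = _run(full_conn, td, Q_o=qo)
    return runs


@pytest.fixture(scope="session")
def poisson_raster():
    """Independent-Poisson null: 100 neurons, 5 Hz, 100 s (~5e4 spikes)."""
    return generate_poisson_raster(100, 5.0, 100_000.0, seed=11)
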