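"""Simulator: connectivity, synaptic kernel, integration accuracy,
refractoriness and reproducibility."""

import numpy as np
import pytest
from scipy.integrate import quad

from eicrit import NetworkConfig, build_connectivity, simulate_network, run_trials
from eicrit import synaptic_kernel
from eicrit.netsim import SimulationInstabilityError

from conftest import scaled_config


# ---------------------------------------------------------------- connectivity

def test_complete_graph_at_density_one():
    cfg = NetworkConfig(N=5, p=1.0, n_o=4)
    conn = build_connectivity(cfg, seed=0)
    assert conn.n_edges == 5 * 4
    assert np.all(conn.in_degrees() == 4)
    for j in range(5):
        assert j not in conn.targets(j)


def test_empty_graph_at_density_zero():
    cfg = NetworkConfig(N=10, p=0.0, n_o=1)
    conn = build_connectivity(cfg, seed=0)
    assert conn.n_edges == 0


def test_invalid_density_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(N=10, p=1.5)
    with pytest.raises(ValueError):
        NetworkConfig(N=10, p=-0.1)


def test_in_degree_binomial_moments(full_conn):
    """Each neuron's E in-degree is Binomial(N_E - [i is E], p)."""
    deg_E = full_conn.in_degrees("E")
    # mean over 10^4 neurons: SE = sqrt(p(1-p)N_E / N) ~ 0.36
    assert abs(deg_E.mean() - 0.2 * 8000) < 5
    assert abs(deg_E.var() / (0.2 * 0.8 * 8000) - 1) < 0.1


def test_connectivity_reproducible():
    cfg = NetworkConfig(N=200, n_o=32)
    a = build_connectivity(cfg, seed=3)
    b = build_connectivity(cfg, seed=3)
    assert np.array_equal(a.indices, b.indices)
    c = build_connectivity(cfg, seed=4)
    assert not np.array_equal(a.indices, c.indices)


# ---------------------------------------------------------------- kernel

def test_kernel_is_normalized_density():
    val, _ = quad(synaptic_kernel, 0, 200, args=(0.5, 2.0))
    assert val == pytest.approx(1.0, abs=1e-9)
    assert synaptic_kernel(0.0, 0.5, 2.0) == 0.0


def test_kernel_peak_location():
    tr, td = 0.5, 2.0
    t_star = tr * td / (td - tr) * np.log(td / tr)
    t = np.linspace(0, 10, 20001)
    f = synaptic_kernel(t, tr, td)
    assert t[np.argmax(f)] == pytest.approx(t_star, abs=1e-3)
    assert t_star == pytest.approx(0.924, abs=1e-3)


def test_kernel_degenerate_time_constants_rejected():
    with pytest.raises(ValueError):
        synaptic_kernel(1.0, 2.0, 2.0)
    with pytest.raises(ValueError):
        synaptic_kernel(1.0, 3.0, 2.0)


# ---------------------------------------------------------------- integration

def test_quiescent_without_input():
    cfg = NetworkConfig(N=20, n_o=10, Q_o=0.0, duration=200.0, discard=0.0)
    conn = build_connectivity(cfg, 0)
    V0 = np.full(20, -70.0)
    raster, trace = simulate_network(cfg, conn, seed=1, V0=V0, record_n=None)
    assert raster.n_spikes == 0
    assert np.allclose(trace.values, -70.0, atol=1e-12)


def test_single_neuron_isi_convergence_order():
    """The closed-form LIF period is recovered with error shrinking at
    second order as dt is refined."""
    expect = 2.0 + 20.0 * np.log(2.0)
    errs = []
    for dt in (0.04, 0.02, 0.01):
        cfg = NetworkConfig(N=1, n_o=1, Q_o=0.0, I_const=1.5, dt=dt,
                            duration=400.0, discard=0.0)
        conn = build_connectivity(cfg, 0)
        raster, _ = simulate_network(cfg, conn, seed=0, V0=np.array([-70.0]))
        isis = np.diff(raster.times)
        errs.append(np.abs(isis - expect).max())
    # ratio ~4 per halving for a 2nd-order scheme; allow >= 2.5
    assert errs[0] / max(errs[1], 1e-15) > 2.5
    assert errs[1] / max(errs[2], 1e-15) > 2.5


def test_synaptic_charge_per_spike_equals_weight():
    """Integrating the post-synaptic current response to one isolated
    presynaptic spike returns the synaptic weight (kernel has unit area)."""
    cfg = NetworkConfig(N=2, frac_E=0.5, p=1.0, n_o=1, Q_o=0.0,
                        duration=60.0, discard=0.0, dt=0.01)
    conn = build_connectivity(cfg, 0)
    # neuron 0 (E) starts just above threshold -> one spike; neuron 1 (I)
    # receives it through the E kernel with weight J_IE
    raster, trace = simulate_network(cfg, conn, seed=0,
                                     V0=np.array([-49.9, -70.0]),
                                     record_n=None, record_dt=0.01)
    assert raster.n_spikes == 1 and raster.ids[0] == 0
    t = trace.sample_times
    v1 = trace.values[1]
    leak = (cfg.V_rest_I - v1) / cfg.tau_m_I
    charge = (v1[-1] - (-70.0)) - np.trapezoid(leak, t)
    assert charge == pytest.approx(cfg.J_IE, rel=2e-3)


def test_no_isi_below_refractory_period():
    cfg = scaled_config(1000, duration=1500.0, discard=0.0, seed=5)
    conn = build_connectivity(cfg, 5)
    raster, _ = simulate_network(cfg, conn, seed=6)
    assert raster.n_spikes > 100
    for pop, t_ref in (("E", cfg.t_ref_E), ("I", cfg.t_ref_I)):
        for nid in raster.neuron_ids(pop)[::37]:
            tt = raster.spike_times_of(int(nid))
            if tt.size > 1:
                assert np.diff(tt).min() >= t_ref - 1e-9


def test_balanced_weight_ratio_sequence_monotone():
    cfg = NetworkConfig()
    ratios = [cfg.J_EO / cfg.J_IO, cfg.J_EI / cfg.J_II, cfg.J_EE / cfg.J_IE]
    assert ratios == pytest.approx([0.625, 0.5625, 0.5])
    assert ratios[0] > ratios[1] > ratios[2]


def test_instability_guard_names_dt():
    cfg = NetworkConfig(N=1, n_o=1, Q_o=0.0, I_const=1e5, duration=50.0,
                        discard=0.0, V_th=1e9, V_reset=0.0)
    conn = build_connectivity(cfg, 0)
    with pytest.raises(SimulationInstabilityError, match="dt"):
        simulate_network(cfg, conn, seed=0, V0=np.array([-70.0]))


# ---------------------------------------------------------------- trials

def test_run_trials_deterministic_and_distinct():
    cfg = scaled_config(400, duration=600.0, discard=100.0, seed=9)
    a = run_trials(cfg, 2, base_seed=13)
    b = run_trials(cfg, 2, base_seed=13)
    for (ra, _), (rb, _) in zip(a, b):
        assert np.array_equal(ra.times, rb.times)
        assert np.array_equal(ra.ids, rb.ids)
    # distinct trials differ (initial conditions and drive)
    assert not np.array_equal(a[0][0].times, a[1][0].times)


def test_run_trials_rejects_zero_trials():
    with pytest.raises(ValueError):
        run_trials(NetworkConfig(N=100, n_o=16), 0)


def test_trial_rate_dispersion_is_small():
    """Trial-to-trial dispersion of the mean E rate stays below 10% of the
    mean (trials differ only in initial potentials and drive)."""
    cfg = scaled_config(2500, duration=2000.0, discard=500.0, seed=21)
    out = run_trials(cfg, 3, base_seed=17)
    rates = [raster.rate_hz("E") for raster, _ in out]
    assert np.std(rates) / np.mean(rates) < 0.10
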