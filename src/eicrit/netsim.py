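"""Current-based leaky integrate-and-fire E-I network simulator.

The membrane potential of neuron i (population alpha in {E, I}) obeys

    dV_i/dt = (V_rest^a - V_i)/tau_a
              + J_aO * sum_{j in ext} (F_E * s_j)(t)
              + J_aE * sum_{j in dE_i} (F_E * s_j)(t)
              + J_aI * sum_{j in dI_i} (F_I * s_j)(t),

where s_j is the presynaptic spike train and F is the normalized
bi-exponential synaptic filter.  When V crosses V_th a spike is emitted,
V is reset to V_reset and synaptic integration is halted for the
refractory period.  External drive is n_o independent Poisson sources at
rate Q_o per neuron, filtered through the excitatory kernel.
"""

from __future__ import annotations

import numpy as np

from . import _simcore
from .config import NetworkConfig, Connectivity, build_connectivity
from .raster import SpikeRaster, VoltageTrace

__all__ = [
    "synaptic_kernel",
    "build_connectivity",
    "simulate_network",
    "run_trials",
    "SimulationInstabilityError",
]


class SimulationInstabilityError(RuntimeError):
    pass


def synaptic_kernel(t, tau_r: float, tau_d: float):
    """Bi-exponential synaptic filter, a unit-area density (per ms):

        F(t) = [exp(-t/tau_d) - exp(-t/tau_r)] / (tau_d - tau_r),  t >= 0.

    Requires 0 < tau_r < tau_d; the degenerate alpha-function limit
    tau_r = tau_d is not implemented.
    """
    if not (0 < tau_r < tau_d):
        raise ValueError(
            f"need 0 < tau_r < tau_d (got tau_r={tau_r}, tau_d={tau_d}); "
            "the alpha-function limit tau_r == tau_d is not supported")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal: t >= 0 required")
    return (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / (tau_d - tau_r)


def _per_neuron_arrays(config: NetworkConfig):
    N, N_E = config.N, config.N_E
    is_E = np.arange(N) < N_E
    tau_m = np.where(is_E, config.tau_m_E, config.tau_m_I)
    v_rest = np.where(is_E, config.V_rest_E, config.V_rest_I)
    t_ref = np.where(is_E, config.t_ref_E, config.t_ref_I).astype(float)
    # read-out coefficients: weight / (tau_d - tau_r) per input class
    cO = np.where(is_E, config.J_EO, config.J_IO) / (config.tau_d_E - config.tau_r)
    cE = np.where(is_E, config.J_EE, config.J_IE) / (config.tau_d_E - config.tau_r)
    cI = np.where(is_E, config.J_EI, config.J_II) / (config.tau_d_I - config.tau_r)
    return tau_m, v_rest, t_ref, cO, cE, cI


def simulate_network(config: NetworkConfig,
                     conn: Connectivity | None = None,
                     seed: int | None = None,
                     V0: np.ndarray | None = None,
                     record_n: int | None = 2000,
                     record_dt: float = 1.0,
                     spike_buffer_hz: float = 60.0,
                     ) -> tuple[SpikeRaster, VoltageTrace]:
    """Integrate the network and return its spike raster and voltage trace.

    Parameters
    ----------
    conn : connectivity; built from ``config.seed`` when omitted.
    seed : integration seed (initial potentials + Poisson drive); defaults
        to ``config.seed``.
    V0 : initial potentials; uniform in [V_reset, V_th] when omitted.
    record_n : number of neurons whose voltage is sampled every
        ``record_dt`` ms (a per-population proportional, evenly spaced
        subset); ``None`` records all neurons.
    spike_buffer_hz : sizing guess (spikes per neuron-second) for the
        preallocated spike buffer; grown automatically on overflow.
    """
    if seed is None:
        seed = config.seed
    if conn is not None and conn.N != config.N:
        raise ValueError("connectivity dimensions inconsistent with config")
    if conn is None:
        conn = build_connectivity(config, config.seed)

    N = config.N
    rng = np.random.default_rng(seed)
    if V0 is None:
        V = rng.uniform(config.V_reset, config.V_th, size=N)
    else:
        V = np.array(V0, dtype=float)
        if V.shape != (N,):
            raise ValueError("V0 must have shape (N,)")

    tau_m, v_rest, t_ref, cO, cE, cI = _per_neuron_arrays(config)
    if min(config.t_ref_E, config.t_ref_I) <= config.dt:
        raise ValueError("refractory periods must exceed dt")
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    dec_dE = float(np.exp(-dt / config.tau_d_E))
    dec_dI = float(np.exp(-dt / config.tau_d_I))
    dec_r = float(np.exp(-dt / config.tau_r))
    lam_ext = config.n_o * config.Q_o_per_ms * dt

    # voltage recording: evenly spaced subset within each population
    if record_n is None or record_n >= N:
        rec_idx = np.arange(N, dtype=np.int64)
    else:
        n_rec_E = int(round(record_n * config.frac_E))
        n_rec_I = record_n - n_rec_E
        idx_E = np.linspace(0, config.N_E - 1, max(n_rec_E, 1)).astype(np.int64)
        idx_I = config.N_E + np.linspace(0, config.N_I - 1,
                                         max(n_rec_I, 1)).astype(np.int64)
        rec_idx = np.unique(np.concatenate([idx_E, idx_I]))
    rec_every = max(1, int(round(record_dt / dt)))
    n_samples = n_steps // rec_every
    rec_out = np.empty((rec_idx.size, n_samples), dtype=np.float64)

    sim_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    buf = int(max(1000, N * (config.duration / 1000.0) * spike_buffer_hz))
    while True:
        spike_t = np.empty(buf, dtype=np.float64)
        spike_i = np.empty(buf, dtype=np.int64)
        Vwork = V.copy()
        status, n_sp = _simcore.integrate(
            Vwork, t_ref, tau_m, v_rest,
            config.V_th, config.V_reset, config.I_const,
            cO, cE, cI, dec_dE, dec_dI, dec_r,
            config.tau_d_E, config.tau_d_I, config.tau_r,
            conn.indptr, conn.indices, config.N_E,
            lam_ext, dt, n_steps,
            rec_idx, rec_every, rec_out, spike_t, spike_i, sim_seed)
        if status == _simcore.STATUS_OVERFLOW:
            buf *= 4
            continue
        break
    if status == _simcore.STATUS_UNSTABLE:
        raise SimulationInstabilityError(
            f"membrane potential exceeded 1e3 mV; dt={dt} ms is too coarse "
            "for these parameters")

    population = np.array(["E"] * config.N_E + ["I"] * config.N_I, dtype=object)
    order = np.argsort(spike_t[:n_sp], kind="stable")
    raster = SpikeRaster(spike_t[:n_sp][order], spike_i[:n_sp][order],
                         population, t_start=0.0, t_end=config.duration,
                         discard=config.discard,
                         meta={"config_hash": config.config_hash(),
                               "seed": seed, "conn_seed": conn.seed})
    trace = VoltageTrace(rec_out,
                         sample_times=(np.arange(n_samples) + 1) * rec_every * dt,
                         neuron_ids=rec_idx,
                         population=population[rec_idx],
                         discard=config.discard)
    return raster, trace


def run_trials(config: NetworkConfig, n_trials: int, base_seed: int | None = None,
               resample_connectivity: bool = False, **sim_kwargs):
    """Run independent trials with distinct derived seeds and uniform-random
    initial membrane potentials; connectivity is shared across trials unless
    ``resample_connectivity``."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if base_seed is None:
        base_seed = config.seed
    trial_seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_trials)
    trial_seeds = (trial_seeds % (2**31)).astype(np.int64)
    conn = None
    out = []
    for k in range(n_trials):
        if conn is None or resample_connectivity:
            conn_seed = int(trial_seeds[n_trials + k]) if resample_connectivity \
                else config.seed
            conn = build_connectivity(config, conn_seed)
        try:
            out.append(simulate_network(config, conn, seed=int(trial_seeds[k]),
                                        **sim_kwargs))
        except SimulationInstabilityError as err:
            raise SimulationInstabilityError(f"trial {k}: {err}") from err
    return out
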