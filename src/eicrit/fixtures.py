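"""Synthetic spike-data generators with known ground truth.

These emulate the statistical structure of the data the statistics
modules consume — independent Poisson spiking (asynchronous null),
oscillation-modulated inhomogeneous Poisson spiking (sparse synchrony),
telegraph up-down modulated spiking with heterogeneous rates (cultured
slice style, ~0.1 Hz alternation), and count series with planted
truncated power-law avalanches — so every estimator is testable without
running the network simulator.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

import numpy as np

from .avalanche import sample_truncated_powerlaw
from .raster import SpikeRaster
from .spikestats import CountSeries

__all__ = [
    "generate_poisson_raster",
    "generate_modulated_raster",
    "generate_updown_raster",
    "generate_powerlaw_avalanche_counts",
]


def _raster_from_trains(trains, n_neurons, duration, meta) -> SpikeRaster:
    times = np.concatenate(trains) if trains else np.empty(0)
    ids = np.concatenate([np.full(t.size, k, dtype=np.int64)
                          for k, t in enumerate(trains)]) if trains else np.empty(0, np.int64)
    order = np.argsort(times, kind="stable")
    population = np.array(["E"] * n_neurons, dtype=object)
    return SpikeRaster(times[order], ids[order], population,
                       t_start=0.0, t_end=duration, discard=0.0, meta=meta)


def generate_poisson_raster(n_neurons: int, rate_hz: float, duration_ms: float,
                            seed: int) -> SpikeRaster:
    """Independent homogeneous Poisson trains at ``rate_hz`` per neuron."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    lam = rate_hz / 1000.0
    trains = []
    for _ in range(n_neurons):
        n = rng.poisson(lam * duration_ms)
        trains.append(np.sort(rng.uniform(0, duration_ms, size=n)))
    return _raster_from_trains(trains, n_neurons, duration_ms,
                               {"generator": "poisson", "rate_hz": rate_hz,
                                "seed": seed})


def generate_modulated_raster(n_neurons: int, rate_hz: float,
                              duration_ms: float, mod_freq_hz: float,
                              mod_depth: float, seed: int) -> SpikeRaster:
    """Inhomogeneous Poisson trains with sinusoidally modulated rate
    r(t) = rate * (1 + depth sin(2 pi f t)), generated by thinning; the
    population-rate PSD peaks at the modulation frequency.  Depth 0
    reduces to the homogeneous generator."""
    if not (0 <= mod_depth <= 1):
        raise ValueError("modulation depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lam_max = rate_hz / 1000.0 * (1 + mod_depth)
    omega = 2 * np.pi * mod_freq_hz / 1000.0
    trains = []
    for _ in range(n_neurons):
        n = rng.poisson(lam_max * duration_ms)
        cand = np.sort(rng.uniform(0, duration_ms, size=n))
        accept = rng.random(n) < (1 + mod_depth * np.sin(omega * cand)) / (1 + mod_depth)
        trains.append(cand[accept])
    return _raster_from_trains(trains, n_neurons, duration_ms,
                               {"generator": "modulated_oscillation",
                                "rate_hz": rate_hz, "mod_freq_hz": mod_freq_hz,
                                "mod_depth": mod_depth, "seed": seed})


def generate_updown_raster(n_neurons: int, up_rate_hz: float,
                           down_rate_hz: float, duration_ms: float,
                           switch_period_ms: float = 5000.0,
                           rate_sigma_log: float = 1.0,
                           start_up: bool = False,
                           seed: int = 0):
    """Telegraph up-down modulated Poisson raster with heterogeneous
    per-neuron lognormal rate multipliers (sigma of log = ``rate_sigma_log``,
    median 1).  Epochs alternate deterministically every
    ``switch_period_ms`` (default 5 s, i.e. a 0.1 Hz up-down cycle).

    Returns ``(raster, switch_times_ms)`` where switch_times are the
    ground-truth epoch boundaries."""
    rng = np.random.default_rng(seed)
    mult = np.exp(rng.normal(0.0, rate_sigma_log, size=n_neurons))
    mult /= np.median(mult)
    edges = np.arange(0.0, duration_ms + switch_period_ms, switch_period_ms)
    edges[-1] = min(edges[-1], duration_ms)
    trains = [[] for _ in range(n_neurons)]
    up = start_up
    for lo, hi in zip(edges[:-1], edges[1:]):
        base = up_rate_hz if up else down_rate_hz
        for i in range(n_neurons):
            lam = base * mult[i] / 1000.0
            n = rng.poisson(lam * (hi - lo))
            if n:
                trains[i].append(rng.uniform(lo, hi, size=n))
        up = not up
    trains = [np.sort(np.concatenate(t)) if t else np.empty(0) for t in trains]
    raster = _raster_from_trains(trains, n_neurons, duration_ms,
                                 {"generator": "telegraph_updown",
                                  "up_rate_hz": up_rate_hz,
                                  "down_rate_hz": down_rate_hz,
                                  "switch_period_ms": switch_period_ms,
                                  "seed": seed})
    return raster, edges[1:-1]


def generate_powerlaw_avalanche_counts(n_avalanches: int, tau: float,
                                       x_min: int = 1, x_max: int = 10_000,
                                       dt: float = 1.0,
                                       seed: int = 0) -> CountSeries:
    """Count series with planted avalanches: sizes drawn from a truncated
    discrete power law P(S) ~ S^-tau on [x_min, x_max], spikes spread over
    durations T = max(1, round(sqrt(S))) (the S ~ T^2 allocation, one
    spike guaranteed per occupied bin), avalanches separated by single
    empty bins."""
    if tau <= 1:
        raise ValueError("exponent must exceed 1")
    rng = np.random.default_rng(seed)
    sizes = sample_truncated_powerlaw(n_avalanches, tau, x_min, x_max, rng)
    chunks = [np.zeros(1, dtype=np.int64)]
    for S in sizes:
        T = max(1, int(round(np.sqrt(S))))
        counts = np.ones(T, dtype=np.int64)
        extra = int(S) - T
        if extra > 0:
            counts += rng.multinomial(extra, np.full(T, 1.0 / T))
        chunks.append(counts)
        chunks.append(np.zeros(1, dtype=np.int64))
    return CountSeries(np.concatenate(chunks), dt=dt, scope="population",
                       n_units=1)
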