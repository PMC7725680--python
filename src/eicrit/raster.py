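"""Spike raster and voltage trace containers.

``SpikeRaster`` is the interchange object between the simulator, the
fixture generators and every statistics module: timestamped spikes (ms)
with a population label per neuron id, plus the record span and the length
of the initial transient flagged for exclusion from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "VoltageTrace"]


@dataclass
class SpikeRaster:
    times: np.ndarray               # spike times, ms, globally sorted
    ids: np.ndarray                 # neuron ids, aligned with times
    population: np.ndarray          # per-neuron label array of "E"/"I"
    t_start: float                  # ms
    t_end: float                    # ms
    discard: float = 0.0            # initial ms flagged as transient
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.population = np.asarray(self.population)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must be aligned")
        if self.times.size and not np.all(np.diff(self.times) >= 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.ids = self.ids[order]

    @property
    def n_neurons(self) -> int:
        return int(self.population.size)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def neuron_ids(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_neurons)
        return np.flatnonzero(self.population == population)

    def select(self, population: str | None = None,
               exclude_discard: bool = True) -> "SpikeRaster":
        """Restrict to one population and/or the post-transient window.
        Neuron ids and the label array are preserved."""
        mask = np.ones(self.times.size, dtype=bool)
        t0 = self.t_start
        if exclude_discard and self.discard > 0:
            t0 = self.t_start + self.discard
            mask &= self.times >= t0
        if population is not None:
            keep = self.population[self.ids] == population
            mask &= keep
        return SpikeRaster(self.times[mask], self.ids[mask], self.population,
                           t_start=t0, t_end=self.t_end, discard=0.0,
                           meta=dict(self.meta))

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def rate_hz(self, population: str | None = None,
                exclude_discard: bool = True) -> float:
        """Time-averaged per-neuron firing rate in Hz."""
        sub = self.select(population, exclude_discard)
        n = sub.neuron_ids(population).size if population else sub.n_neurons
        span_s = (sub.t_end - sub.t_start) / 1000.0
        if n == 0 or span_s <= 0:
            raise ValueError("empty population or span")
        return sub.n_spikes / n / span_s

    # --- I/O -----------------------------------------------------------
    def to_csv(self, spikes_path, neurons_path=None) -> None:
        pd.DataFrame({"time_ms": self.times, "neuron_id": self.ids}).to_csv(
            spikes_path, index=False)
        if neurons_path is not None:
            pd.DataFrame({"neuron_id": np.arange(self.n_neurons),
                          "population": self.population}).to_csv(
                neurons_path, index=False)

    @classmethod
    def from_csv(cls, spikes_path, neurons_path=None,
                 t_start: float | None = None,
                 t_end: float | None = None) -> "SpikeRaster":
        """Read a generic two-column spike file.  A ``time_s`` header is
        autodetected and converted to ms."""
        df = pd.read_csv(spikes_path)
        cols = {c.lower(): c for c in df.columns}
        if "time_ms" in cols:
            times = df[cols["time_ms"]].to_numpy(float)
        elif "time_s" in cols:
            times = df[cols["time_s"]].to_numpy(float) * 1000.0
        else:  # fall back to first two columns
            times = df.iloc[:, 0].to_numpy(float)
        if "neuron_id" in cols:
            ids = df[cols["neuron_id"]].to_numpy(np.int64)
        else:
            ids = df.iloc[:, 1].to_numpy(np.int64)
        n = int(ids.max()) + 1 if ids.size else 0
        if neurons_path is not None:
            tab = pd.read_csv(neurons_path)
            n = max(n, int(tab["neuron_id"].max()) + 1)
            population = np.array(["E"] * n, dtype=object)
            population[tab["neuron_id"].to_numpy()] = tab["population"].to_numpy()
        else:
            population = np.array(["E"] * n, dtype=object)
        if t_start is None:
            t_start = float(times.min()) if times.size else 0.0
        if t_end is None:
            t_end = float(times.max()) if times.size else 0.0
        return cls(times, ids, population, t_start=t_start, t_end=t_end)


@dataclass
class VoltageTrace:
    """Membrane potentials sampled on a regular grid (default every 1 ms)
    for a recorded subset of neurons.  Samples follow the post-reset
    convention, so every value is <= V_th."""

    values: np.ndarray              # (n_recorded, n_samples) mV
    sample_times: np.ndarray        # ms
    neuron_ids: np.ndarray          # recorded neuron ids
    population: np.ndarray          # labels of the recorded neurons
    discard: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)

    def select(self, population: str | None = None,
               exclude_discard: bool = True) -> "VoltageTrace":
        rows = np.ones(self.neuron_ids.size, dtype=bool)
        if population is not None:
            rows = self.population == population
        cols = np.ones(self.sample_times.size, dtype=bool)
        if exclude_discard and self.discard > 0:
            cols = self.sample_times >= self.sample_times[0] + self.discard
        return VoltageTrace(self.values[np.ix_(rows, cols)],
                            self.sample_times[cols],
                            self.neuron_ids[rows],
                            self.population[rows], discard=0.0)
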