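"""Network configuration and connectivity.

All potentials are in mV, all times in ms, all rates at the configuration
surface in Hz (converted to per-ms internally).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["NetworkConfig", "Connectivity", "build_connectivity"]


@dataclass
class NetworkConfig:
    """Microscopic parameters of the current-based leaky IF E-I network.

    The defaults reproduce the reference parameter set: a random network of
    N = 10^4 neurons (80% excitatory) at density p = 0.2, driven by
    n_o = p*N_E external Poisson sources per neuron at Q_o = 5 Hz each,
    with bi-exponential synaptic filtering (rise 0.5 ms, excitatory decay
    2 ms) and weights satisfying the balanced condition.
    """

    N: int = 10_000
    frac_E: float = 0.8
    p: float = 0.2
    n_o: int | None = None          # default p * N * frac_E
    Q_o: float = 5.0                # Hz per external source

    # synaptic weights, mV
    J_EO: float = 0.45
    J_IO: float = 0.72
    J_EE: float = 0.36
    J_IE: float = 0.72
    J_EI: float = -0.81
    J_II: float = -1.44

    # potentials, mV
    V_rest_E: float = -70.0
    V_rest_I: float = -70.0
    V_th: float = -50.0
    V_reset: float = -60.0

    # time constants, ms
    tau_m_E: float = 20.0
    tau_m_I: float = 10.0
    tau_r: float = 0.5
    tau_d_E: float = 2.0
    tau_d_I: float = 1.0
    t_ref_E: float = 2.0
    t_ref_I: float = 1.0
    tau_l_E: float = 0.0            # transmission delays carried but must be 0
    tau_l_I: float = 0.0

    # constant external current, mV/ms (0 in the reference model; nonzero
    # values support single-neuron closed-form checks)
    I_const: float = 0.0

    # integration
    dt: float = 0.05                # ms
    duration: float = 16_000.0      # ms
    discard: float = 1_000.0        # ms flagged for exclusion from statistics
    seed: int = 0

    def __post_init__(self) -> None:
        # p = 0 (uncoupled neurons) is allowed as a degenerate but useful case
        if not (0 <= self.p <= 1):
            raise ValueError(f"connection density p must be in [0, 1], got {self.p}")
        if not (0 < self.frac_E < 1):
            raise ValueError("frac_E must be in (0, 1)")
        if self.n_o is None:
            self.n_o = int(round(self.p * self.N * self.frac_E))
        if self.J_EI >= 0 or self.J_II >= 0:
            raise ValueError("inhibitory weights J_EI, J_II must be negative")
        if min(self.J_EO, self.J_IO, self.J_EE, self.J_IE) <= 0:
            raise ValueError("excitatory weights J_EO, J_IO, J_EE, J_IE must be positive")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must lie below V_th")
        if self.tau_r >= min(self.tau_d_E, self.tau_d_I):
            raise ValueError(
                "tau_r must be smaller than both synaptic decay times "
                f"(tau_r={self.tau_r}, tau_d_E={self.tau_d_E}, tau_d_I={self.tau_d_I})"
            )
        if self.dt >= self.tau_r:
            raise ValueError(f"dt={self.dt} must resolve the synaptic rise time {self.tau_r}")
        if self.tau_l_E != 0.0 or self.tau_l_I != 0.0:
            raise NotImplementedError("nonzero transmission delays are out of scope")

    # --- derived sizes -------------------------------------------------
    @property
    def N_E(self) -> int:
        return int(round(self.N * self.frac_E))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def n_E(self) -> float:
        """Mean recurrent excitatory in-degree."""
        return self.p * self.N_E

    @property
    def n_I(self) -> float:
        """Mean recurrent inhibitory in-degree."""
        return self.p * self.N_I

    @property
    def Q_o_per_ms(self) -> float:
        return self.Q_o / 1000.0

    # --- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if isinstance(v, np.floating):
                v = float(v)
            elif isinstance(v, np.integer):
                v = int(v)
            out[k] = v
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set (for provenance)."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Connectivity:
    """Directed Erdos-Renyi adjacency in CSR layout by presynaptic neuron.

    ``indices[indptr[j]:indptr[j+1]]`` are the postsynaptic targets of
    neuron j.  Neurons 0..N_E-1 are excitatory, the rest inhibitory, so the
    presynaptic population of an edge is implied by the row index.
    """

    indptr: np.ndarray
    indices: np.ndarray
    N: int
    N_E: int
    p: float
    seed: int

    def out_degree(self, j: int) -> int:
        return int(self.indptr[j + 1] - self.indptr[j])

    def targets(self, j: int) -> np.ndarray:
        return self.indices[self.indptr[j]:self.indptr[j + 1]]

    def in_degrees(self, presyn: str | None = None) -> np.ndarray:
        """In-degree of every neuron, optionally restricted to presynaptic
        population ``"E"`` or ``"I"``."""
        if presyn == "E":
            rows = slice(0, self.N_E)
        elif presyn == "I":
            rows = slice(self.N_E, self.N)
        elif presyn is None:
            rows = slice(0, self.N)
        else:
            raise ValueError("presyn must be 'E', 'I', or None")
        lo, hi = self.indptr[rows.start], self.indptr[rows.stop]
        return np.bincount(self.indices[lo:hi], minlength=self.N)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size)


def build_connectivity(config: NetworkConfig, seed: int | None = None) -> Connectivity:
    """Draw a directed Erdos-Renyi graph: each ordered pair (j -> i), j != i,
    is an edge independently with probability p.  Reproducible for a fixed
    seed."""
    if seed is None:
        seed = config.seed
    N, p = config.N, config.p
    rng = np.random.default_rng(seed)
    rows = []
    indptr = np.zeros(N + 1, dtype=np.int64)
    for j in range(N):
        mask = rng.random(N) < p
        mask[j] = False  # no self-edges
        tgt = np.flatnonzero(mask).astype(np.int32)
        rows.append(tgt)
        indptr[j + 1] = indptr[j] + tgt.size
    indices = np.concatenate(rows) if rows else np.empty(0, dtype=np.int32)
    return Connectivity(indptr=indptr, indices=indices, N=N, N_E=config.N_E,
                        p=p, seed=seed)
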