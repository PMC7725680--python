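"""Semi-analytical mean-field (field-equation) description of the network.

The macroscopic state is X = (V_E, V_I, Phi_E, dPhi_E, Phi_I, dPhi_I):
population-mean membrane potentials plus the filtered population inputs
Phi_a and their derivatives.  The mean firing rate of population a is
closed through the logistic transfer function

    Q_a(V) = 1 / (1 + exp((V_th - V) * pi / (sqrt(3) * sigma_a))),

a smooth (erf -> tanh) approximation of the suprathreshold fraction of a
Gaussian voltage distribution with mean V and SD sigma_a.  The dynamics
are

    dV_a/dt = (V_rest^a - V_a)/tau_a + J_aO n_o Q_o + J_aE Phi_E
              + J_aI Phi_I  [+ J_aO sqrt(n_o Q_o / N_a) xi_a(t)],
    (tau_d^a d/dt + 1)(tau_r d/dt + 1) Phi_a = n_a Q_a(V_a).

Rates are per-ms internally; Hz at all public interfaces that say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize

from .config import NetworkConfig

__all__ = [
    "FieldParams", "FixedPoint", "HopfScanResult",
    "transfer_rate", "transfer_rate_derivative", "estimate_sigma",
    "sigma_diffusion", "check_balanced_condition", "solve_balanced_rates",
    "solve_fixed_point", "jacobian", "hopf_scan", "integrate_field",
    "field_population_ff", "calibrate_sigma_from_run",
]

_SQRT3 = np.sqrt(3.0)


@dataclass
class FieldParams:
    """Macroscopic parameterization.  sigma_E/sigma_I are the effective
    voltage SDs (mV) calibrated from an asynchronous-state simulation or
    from the diffusion closed form; rates are per ms."""

    sigma_E: float
    sigma_I: float
    n_E: float
    n_I: float
    n_o: float
    Q_o: float                    # per ms
    J_EO: float
    J_IO: float
    J_EE: float
    J_IE: float
    J_EI: float
    J_II: float
    tau_m_E: float
    tau_m_I: float
    tau_r: float
    tau_d_E: float
    tau_d_I: float
    N_E: int
    N_I: int
    V_th: float
    V_rest_E: float
    V_rest_I: float

    def __post_init__(self) -> None:
        if self.sigma_E <= 0 or self.sigma_I <= 0:
            raise ValueError("sigma_a must be positive")
        for name in ("tau_m_E", "tau_m_I", "tau_r", "tau_d_E", "tau_d_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_network_config(cls, cfg: NetworkConfig,
                            sigma_E: float, sigma_I: float) -> "FieldParams":
        return cls(sigma_E=sigma_E, sigma_I=sigma_I,
                   n_E=cfg.n_E, n_I=cfg.n_I, n_o=cfg.n_o,
                   Q_o=cfg.Q_o_per_ms,
                   J_EO=cfg.J_EO, J_IO=cfg.J_IO, J_EE=cfg.J_EE,
                   J_IE=cfg.J_IE, J_EI=cfg.J_EI, J_II=cfg.J_II,
                   tau_m_E=cfg.tau_m_E, tau_m_I=cfg.tau_m_I,
                   tau_r=cfg.tau_r, tau_d_E=cfg.tau_d_E, tau_d_I=cfg.tau_d_I,
                   N_E=cfg.N_E, N_I=cfg.N_I,
                   V_th=cfg.V_th, V_rest_E=cfg.V_rest_E, V_rest_I=cfg.V_rest_I)

    def replace(self, **kw) -> "FieldParams":
        d = self.__dict__.copy()
        d.update(kw)
        return FieldParams(**d)


@dataclass
class FixedPoint:
    V_E: float
    V_I: float
    Q_E: float                  # per ms
    Q_I: float                  # per ms
    residual: float
    eigenvalues: np.ndarray     # 6 complex eigenvalues of the Jacobian
    stable: bool


@dataclass
class HopfScanResult:
    tau_dI_grid: np.ndarray
    re_lambda: np.ndarray       # dominant-pair real part, per ms
    freq_hz: np.ndarray         # Im lambda / 2 pi, Hz
    tau_dI_critical: float | None
    bifurcation_found: bool


# ---------------------------------------------------------------------
# transfer function and its calibration
# ---------------------------------------------------------------------

def transfer_rate(V, sigma, V_th):
    """Logistic voltage-to-rate transfer, per ms: the fraction of neurons
    above threshold for a Gaussian voltage cloud of mean V and SD sigma."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    u = (V_th - np.asarray(V, float)) * np.pi / (_SQRT3 * sigma)
    return 1.0 / (1.0 + np.exp(u))


def transfer_rate_derivative(V, sigma, V_th):
    """dQ/dV of :func:`transfer_rate` (per ms per mV)."""
    u = (V_th - np.asarray(V, float)) * np.pi / (_SQRT3 * sigma)
    e = np.exp(u)
    return np.pi * e / (_SQRT3 * sigma * (1.0 + e) ** 2)


def estimate_sigma(V_ss, Q_ss, V_th):
    """Invert the transfer function: the effective voltage SD that maps the
    steady-state mean voltage V_ss onto the steady-state rate Q_ss (per ms).

    sigma = (V_th - V_ss) * pi / (sqrt(3) * ln(1/Q_ss - 1)).
    Exact round trip: transfer_rate(V_ss, sigma, V_th) == Q_ss.
    """
    Q_ss = float(Q_ss)
    if not (0 < Q_ss < 1):
        raise ValueError("Q_ss must be in (0, 1) per ms")
    if Q_ss == 0.5:
        raise ValueError("Q_ss = 0.5 makes the inversion degenerate")
    denom = np.log(1.0 / Q_ss - 1.0)
    sigma = (V_th - float(V_ss)) * np.pi / (_SQRT3 * denom)
    if sigma <= 0:
        raise ValueError(
            f"inconsistent (V_ss={V_ss}, Q_ss={Q_ss}): inferred sigma <= 0")
    return sigma


def sigma_diffusion(J_ao, n_o, Q_o, tau_m, halved: bool = True):
    """Closed-form stationary voltage SD of a leaky integrator driven by
    white noise of intensity J^2 n_o Q_o (Ornstein-Uhlenbeck):

        sigma = J * sqrt(n_o * Q_o * tau_m / 2).

    ``halved=False`` drops the 1/2 factor for comparison.
    """
    if min(J_ao, n_o, Q_o, tau_m) <= 0:
        raise ValueError("all arguments must be positive")
    fac = 2.0 if halved else 1.0
    return J_ao * np.sqrt(n_o * Q_o * tau_m / fac)


def calibrate_sigma_from_run(raster, trace, cfg: NetworkConfig) -> tuple[float, float]:
    """Estimate (sigma_E, sigma_I) from one asynchronous-state simulation:
    time- and population-averaged membrane potential and firing rate over
    the post-transient window, inverted through the transfer function."""
    out = []
    for pop in ("E", "I"):
        sub = trace.select(pop)
        V_ss = float(sub.values.mean())
        Q_ss = raster.rate_hz(pop) / 1000.0
        out.append(estimate_sigma(V_ss, Q_ss, cfg.V_th))
    return out[0], out[1]


# ---------------------------------------------------------------------
# balanced-limit analysis
# ---------------------------------------------------------------------

def check_balanced_condition(J_EO, J_IO, J_EE, J_IE, J_EI, J_II) -> bool:
    """True iff the ratio sequence {J_EO/J_IO, J_EI/J_II, J_EE/J_IE}
    (ratios of magnitudes) is strictly monotone — the condition for a
    unique positive solution of the balanced linear system."""
    for d in (J_IO, J_II, J_IE):
        if d == 0:
            raise ValueError("zero denominator weight")
    r = (abs(J_EO) / abs(J_IO), abs(J_EI) / abs(J_II), abs(J_EE) / abs(J_IE))
    return (r[0] > r[1] > r[2]) or (r[0] < r[1] < r[2])


def solve_balanced_rates(params: FieldParams) -> tuple[float, float]:
    """Large-N balanced limit: solve the linear system

        J_aO n_o Q_o + J_aE n_E Q_E + J_aI n_I Q_I = 0,  a in {E, I},

    for the steady rates (per ms).  Requires the balanced condition."""
    A = np.array([[params.J_EE * params.n_E, params.J_EI * params.n_I],
                  [params.J_IE * params.n_E, params.J_II * params.n_I]])
    b = -np.array([params.J_EO, params.J_IO]) * params.n_o * params.Q_o
    if abs(np.linalg.det(A)) < 1e-12 * abs(A).max() ** 2:
        raise ValueError("singular balanced system")
    Q = np.linalg.solve(A, b)
    if params.Q_o > 0 and np.any(Q <= 0):
        raise ValueError(f"balanced solution not positive: {Q}")
    return float(Q[0]), float(Q[1])


# ---------------------------------------------------------------------
# fixed point, Jacobian, Hopf scan
# ---------------------------------------------------------------------

def _fp_residual(v, params: FieldParams):
    V_E, V_I = v
    Q_E = transfer_rate(V_E, params.sigma_E, params.V_th)
    Q_I = transfer_rate(V_I, params.sigma_I, params.V_th)
    drive_E = params.J_EO * params.n_o * params.Q_o \
        + params.J_EE * params.n_E * Q_E + params.J_EI * params.n_I * Q_I
    drive_I = params.J_IO * params.n_o * params.Q_o \
        + params.J_IE * params.n_E * Q_E + params.J_II * params.n_I * Q_I
    return np.array([(params.V_rest_E - V_E) / params.tau_m_E + drive_E,
                     (params.V_rest_I - V_I) / params.tau_m_I + drive_I])


def _fp_jac2(v, params: FieldParams):
    V_E, V_I = v
    dQ_E = transfer_rate_derivative(V_E, params.sigma_E, params.V_th)
    dQ_I = transfer_rate_derivative(V_I, params.sigma_I, params.V_th)
    return np.array([
        [-1.0 / params.tau_m_E + params.J_EE * params.n_E * dQ_E,
         params.J_EI * params.n_I * dQ_I],
        [params.J_IE * params.n_E * dQ_E,
         -1.0 / params.tau_m_I + params.J_II * params.n_I * dQ_I]])


def solve_fixed_point(params: FieldParams, tol: float = 1e-10) -> FixedPoint:
    """Deterministic steady state of the field equations (the 6-D fixed
    point reduces to a 2-D root problem in (V_E, V_I)); multistart from the
    rest potentials and from the balanced-limit rates mapped through the
    inverse transfer function."""
    starts = [np.array([params.V_rest_E, params.V_rest_I])]
    try:
        Qb = solve_balanced_rates(params)
        if 0 < Qb[0] < 1 and 0 < Qb[1] < 1:
            starts.append(np.array([
                params.V_th - _SQRT3 * params.sigma_E / np.pi * np.log(1 / Qb[0] - 1),
                params.V_th - _SQRT3 * params.sigma_I / np.pi * np.log(1 / Qb[1] - 1)]))
    except ValueError:
        pass
    best = None
    for x0 in starts:
        sol = optimize.root(_fp_residual, x0, args=(params,), jac=_fp_jac2,
                            method="hybr", tol=1e-13)
        res = float(np.max(np.abs(_fp_residual(sol.x, params))))
        if best is None or res < best[1]:
            best = (sol.x, res)
    x, res = best
    if res >= tol:
        raise RuntimeError(f"fixed-point solver residual {res:.2e} >= {tol:.0e}")
    V_E, V_I = float(x[0]), float(x[1])
    Q_E = float(transfer_rate(V_E, params.sigma_E, params.V_th))
    Q_I = float(transfer_rate(V_I, params.sigma_I, params.V_th))
    fp = FixedPoint(V_E, V_I, Q_E, Q_I, residual=res,
                    eigenvalues=np.empty(6, complex), stable=False)
    fp.eigenvalues = np.linalg.eigvals(jacobian(params, fp))
    fp.stable = bool(np.all(fp.eigenvalues.real < 0))
    return fp


def jacobian(params: FieldParams, fp: FixedPoint) -> np.ndarray:
    """Analytic 6x6 Jacobian of the deterministic field equations at the
    fixed point, in the state order (V_E, V_I, Phi_E, dPhi_E, Phi_I,
    dPhi_I).  Rows 3 and 5 are pure shift rows."""
    dQ_E = float(transfer_rate_derivative(fp.V_E, params.sigma_E, params.V_th))
    dQ_I = float(transfer_rate_derivative(fp.V_I, params.sigma_I, params.V_th))
    tE, tI = params.tau_m_E, params.tau_m_I
    tr, tdE, tdI = params.tau_r, params.tau_d_E, params.tau_d_I
    J = np.zeros((6, 6))
    J[0, 0] = -1.0 / tE
    J[0, 2] = params.J_EE
    J[0, 4] = params.J_EI
    J[1, 1] = -1.0 / tI
    J[1, 2] = params.J_IE
    J[1, 4] = params.J_II
    J[2, 3] = 1.0
    J[3, 0] = params.n_E * dQ_E / (tdE * tr)
    J[3, 2] = -1.0 / (tdE * tr)
    J[3, 3] = -(1.0 / tdE + 1.0 / tr)
    J[4, 5] = 1.0
    J[5, 1] = params.n_I * dQ_I / (tdI * tr)
    J[5, 4] = -1.0 / (tdI * tr)
    J[5, 5] = -(1.0 / tdI + 1.0 / tr)
    return J


def _track_overlap(W, V, v_ref):
    """Eigenvalue whose eigenvector best overlaps v_ref."""
    k = int(np.argmax(np.abs(V.conj().T @ v_ref)))
    return W[k], V[:, k]


def hopf_scan(params: FieldParams, tau_dI_grid) -> HopfScanResult:
    """Scan the inhibitory synaptic decay time, solving the fixed point and
    the dominant eigenvalue pair of the 6-D Jacobian at each grid value,
    then refine the Re lambda = 0 crossing by bisection.

    The dominant pair is the one whose real part becomes largest over the
    scan; it is identified at the grid point where max Re lambda peaks
    (where it is unambiguous) and followed outward in both directions by
    eigenvector overlap, which avoids branch-jumping where eigenvalue real
    parts cross.
    """
    grid = np.asarray(tau_dI_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("tau_dI grid must be sorted ascending")
    eigs, vecs = [], []
    for td in grid:
        p = params.replace(tau_d_I=float(td))
        fp = solve_fixed_point(p)
        w, V = np.linalg.eig(jacobian(p, fp))
        eigs.append(w)
        vecs.append(V)
    max_re = np.array([w.real.max() for w in eigs])
    seed_k = int(np.argmax(max_re))
    re = np.empty(grid.size)
    fr = np.empty(grid.size)

    k0 = int(np.argmax(eigs[seed_k].real))
    lam0, v0 = eigs[seed_k][k0], vecs[seed_k][:, k0]
    re[seed_k] = lam0.real
    fr[seed_k] = abs(lam0.imag) / (2 * np.pi) * 1000.0  # per ms -> Hz
    for direction in (-1, 1):
        v_ref = v0
        k = seed_k + direction
        while 0 <= k < grid.size:
            lam, v_ref = _track_overlap(eigs[k], vecs[k], v_ref)
            re[k] = lam.real
            fr[k] = abs(lam.imag) / (2 * np.pi) * 1000.0
            k += direction

    crossing = None
    idx = np.flatnonzero(np.diff(np.sign(re)) > 0)  # - to + crossing
    if idx.size:
        lo, hi = grid[idx[0]], grid[idx[0] + 1]

        def _re(td, v_ref):
            p = params.replace(tau_d_I=float(td))
            fp = solve_fixed_point(p)
            w, V = np.linalg.eig(jacobian(p, fp))
            lam, v = _track_overlap(w, V, v_ref)
            return lam.real, v

        # re-anchor the reference eigenvector at the bracket's upper end
        p_hi = params.replace(tau_d_I=float(hi))
        fp_hi = solve_fixed_point(p_hi)
        w_hi, V_hi = np.linalg.eig(jacobian(p_hi, fp_hi))
        k_hi = int(np.argmax(w_hi.real))
        v_ref = V_hi[:, k_hi]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            r_mid, v_ref = _re(mid, v_ref)
            if r_mid < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6:
                break
        crossing = 0.5 * (lo + hi)
    return HopfScanResult(grid, re, fr, crossing, crossing is not None)


# ---------------------------------------------------------------------
# stochastic field integration
# ---------------------------------------------------------------------

@njit(cache=True)
def _field_em(x0, n_steps, dt, sample_every,
              tau_m_E, tau_m_I, tau_r, tau_d_E, tau_d_I,
              V_rest_E, V_rest_I, V_th, sigma_E, sigma_I,
              J_EO, J_IO, J_EE, J_IE, J_EI, J_II,
              n_o, n_E, n_I, Q_o, noise_E, noise_I, seed):
    np.random.seed(seed)
    sq3 = np.sqrt(3.0)
    VE, VI, PE, dPE, PI, dPI = x0
    n_out = n_steps // sample_every
    out = np.empty((n_out, 6))
    sqdt = np.sqrt(dt)
    m = 0
    for step in range(n_steps):
        QE = 1.0 / (1.0 + np.exp((V_th - VE) * np.pi / (sq3 * sigma_E)))
        QI = 1.0 / (1.0 + np.exp((V_th - VI) * np.pi / (sq3 * sigma_I)))
        dVE = (V_rest_E - VE) / tau_m_E + J_EO * n_o * Q_o + J_EE * PE + J_EI * PI
        dVI = (V_rest_I - VI) / tau_m_I + J_IO * n_o * Q_o + J_IE * PE + J_II * PI
        ddPE = (n_E * QE - PE - (tau_d_E + tau_r) * dPE) / (tau_d_E * tau_r)
        ddPI = (n_I * QI - PI - (tau_d_I + tau_r) * dPI) / (tau_d_I * tau_r)
        VE += dt * dVE + noise_E * sqdt * np.random.normal()
        VI += dt * dVI + noise_I * sqdt * np.random.normal()
        PE += dt * dPE
        dPE += dt * ddPE
        PI += dt * dPI
        dPI += dt * ddPI
        if abs(VE) > 1e3 or abs(VI) > 1e3:
            return out[:m], 1
        if (step + 1) % sample_every == 0 and m < n_out:
            out[m, 0] = VE
            out[m, 1] = VI
            out[m, 2] = PE
            out[m, 3] = dPE
            out[m, 4] = PI
            out[m, 5] = dPI
            m += 1
    return out[:m], 0


def integrate_field(params: FieldParams, duration: float, dt: float = 0.01,
                    noise: bool = True, seed: int = 0,
                    x0: np.ndarray | None = None,
                    sample_dt: float = 1.0):
    """Euler-Maruyama integration of the 6-D field system.

    Noise of amplitude J_aO sqrt(n_o Q_o / N_a) enters only the two voltage
    equations.  Returns ``(t_ms, X, Q)`` with X of shape (n, 6) and Q of
    shape (n, 2) giving (Q_E, Q_I) per ms at the sample instants.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for the field SDE")
    if x0 is None:
        fp = solve_fixed_point(params)
        x0 = np.array([fp.V_E, fp.V_I,
                       params.n_E * fp.Q_E, 0.0, params.n_I * fp.Q_I, 0.0])
    x0 = np.asarray(x0, dtype=float)
    noise_E = params.J_EO * np.sqrt(params.n_o * params.Q_o / params.N_E) if noise else 0.0
    noise_I = params.J_IO * np.sqrt(params.n_o * params.Q_o / params.N_I) if noise else 0.0
    n_steps = int(round(duration / dt))
    sample_every = max(1, int(round(sample_dt / dt)))
    out, status = _field_em(
        x0, n_steps, dt, sample_every,
        params.tau_m_E, params.tau_m_I, params.tau_r,
        params.tau_d_E, params.tau_d_I,
        params.V_rest_E, params.V_rest_I, params.V_th,
        params.sigma_E, params.sigma_I,
        params.J_EO, params.J_IO, params.J_EE, params.J_IE,
        params.J_EI, params.J_II,
        params.n_o, params.n_E, params.n_I, params.Q_o,
        noise_E, noise_I, int(seed) % (2**31))
    if status != 0:
        raise RuntimeError("field integration blew up (|V| > 1e3 mV)")
    t = (np.arange(out.shape[0]) + 1) * sample_every * dt
    Q = np.column_stack([
        transfer_rate(out[:, 0], params.sigma_E, params.V_th),
        transfer_rate(out[:, 1], params.sigma_I, params.V_th)])
    return t, out, Q


def field_population_ff(params: FieldParams, window: float = 50.0,
                        duration: float = 10_000.0, seed: int = 0,
                        dt: float = 0.01, discard: float = 500.0) -> float:
    """Population Fano factor predicted by the field model: Q_E(t) is
    converted to deterministic per-window excitatory population counts
    N_E * mean(Q_E) * window and FF = var/mean of those counts."""
    if window < dt:
        raise ValueError("window must be >= dt")
    t, _, Q = integrate_field(params, duration, dt=dt, noise=True, seed=seed,
                              sample_dt=dt)
    keep = t >= discard
    q = Q[keep, 0]
    per_win = int(round(window / dt))
    n_win = q.size // per_win
    counts = params.N_E * q[:n_win * per_win].reshape(n_win, per_win).mean(axis=1) * window
    mean = counts.mean()
    if mean <= 0:
        raise ValueError("zero mean count: Fano factor undefined")
    return float(counts.var() / mean)
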