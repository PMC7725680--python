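"""Mean-field module: transfer function, sigma calibration, balanced
analysis, fixed points, Jacobian, Hopf scan, field SDE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eicrit import NetworkConfig
from eicrit import meanfield as mf

V_TH = -50.0


def default_params(sigma_E=5.0, sigma_I=6.0, **kw):
    p = mf.FieldParams.from_network_config(NetworkConfig(N=10_000), sigma_E, sigma_I)
    return p.replace(**kw) if kw else p


# ---------------------------------------------------------------- transfer

def test_transfer_midpoint_limits_monotone():
    assert mf.transfer_rate(V_TH, 4.0, V_TH) == 0.5
    v = np.linspace(-120, 20, 300)
    q = mf.transfer_rate(v, 4.0, V_TH)
    assert np.all(np.diff(q) > 0)
    assert q[0] < 1e-8 and q[-1] > 1 - 1e-8


def test_transfer_known_value():
    # V_th - V = 20, sigma = 4: Q = 1/(1 + exp(20 pi / (4 sqrt(3))))
    q = mf.transfer_rate(V_TH - 20, 4.0, V_TH)
    assert q == pytest.approx(1.0 / (1.0 + np.exp(20 * np.pi / (4 * np.sqrt(3)))))
    assert q == pytest.approx(1.15e-4, rel=5e-3)


def test_transfer_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        mf.transfer_rate(-60.0, 0.0, V_TH)


@settings(deadline=None, derandomize=True)
@given(dv=st.floats(0.1, 40.0), q=st.floats(1e-6, 0.499))
def test_sigma_inversion_roundtrip(dv, q):
    """estimate_sigma is the exact algebraic inverse of transfer_rate."""
    sigma = mf.estimate_sigma(V_TH - dv, q, V_TH)
    assert mf.transfer_rate(V_TH - dv, sigma, V_TH) == pytest.approx(q, rel=1e-12)


def test_sigma_known_value_and_degeneracies():
    sigma = mf.estimate_sigma(V_TH - 10, 0.005, V_TH)
    assert sigma == pytest.approx(10 * np.pi / (np.sqrt(3) * np.log(199)), rel=1e-12)
    assert sigma == pytest.approx(3.43, abs=0.01)
    with pytest.raises(ValueError):
        mf.estimate_sigma(V_TH - 10, 0.5, V_TH)
    with pytest.raises(ValueError):
        mf.estimate_sigma(V_TH - 10, 0.9, V_TH)  # inconsistent sign


def test_sigma_diffusion_value_and_scaling():
    s = mf.sigma_diffusion(0.45, 1600, 0.005, 20.0)
    assert s == pytest.approx(0.45 * np.sqrt(80), rel=1e-12)
    assert mf.sigma_diffusion(0.9, 1600, 0.005, 20.0) == pytest.approx(2 * s)
    assert mf.sigma_diffusion(0.45, 1600, 0.02, 20.0) == pytest.approx(2 * s)
    assert mf.sigma_diffusion(0.45, 1600, 0.005, 20.0, halved=False) \
        == pytest.approx(s * np.sqrt(2))


def test_sigma_diffusion_matches_ou_simulation():
    """Stationary SD of a simulated OU process (leaky integrator driven by
    white noise of the matched intensity) agrees with the closed form."""
    from scipy.signal import lfilter
    J, n_o, Q_o, tau = 0.45, 1600, 0.005, 20.0
    rng = np.random.default_rng(4)
    dt = 0.01
    n = 4_000_000
    xi = J * np.sqrt(n_o * Q_o) * np.sqrt(dt) * rng.standard_normal(n)
    v = lfilter([1.0], [1.0, -(1.0 - dt / tau)], xi)
    sd = v[n // 10:].std()
    assert sd == pytest.approx(mf.sigma_diffusion(J, n_o, Q_o, tau), rel=0.02)


# ---------------------------------------------------------------- balance

def test_balanced_condition_cases():
    assert mf.check_balanced_condition(0.45, 0.72, 0.36, 0.72, -0.81, -1.44)
    # swapping |J_EE| and |J_EI| magnitudes breaks monotonicity
    assert not mf.check_balanced_condition(0.45, 0.72, 0.81, 0.72, -0.36, -1.44)
    assert not mf.check_balanced_condition(0.5, 1.0, 0.5, 1.0, -0.5, -1.0)
    with pytest.raises(ValueError):
        mf.check_balanced_condition(0.45, 0.72, 0.36, 0.0, -0.81, -1.44)


def test_balanced_rates_printed_weights():
    """The balanced linear system with the reference weights gives
    (Q_E, Q_I) = (5, 20) Hz at Q_o = 5 Hz, scaling linearly with Q_o."""
    p = default_params()
    qE, qI = mf.solve_balanced_rates(p)
    assert qE * 1000 == pytest.approx(5.0, rel=1e-9)
    assert qI * 1000 == pytest.approx(20.0, rel=1e-9)
    qE0, qI0 = mf.solve_balanced_rates(p.replace(Q_o=0.0))
    assert qE0 == 0.0 and qI0 == 0.0
    qE2, _ = mf.solve_balanced_rates(p.replace(Q_o=2 * p.Q_o))
    assert qE2 == pytest.approx(2 * qE)


# ---------------------------------------------------------------- fixed point

def test_fixed_point_contract_and_tau_invariance():
    p = default_params()
    fps = [mf.solve_fixed_point(p.replace(tau_d_I=td)) for td in (1.0, 3.0, 4.5)]
    for fp in fps:
        assert fp.residual < 1e-10
        assert 0 < fp.Q_E < 1 and 0 < fp.Q_I < 1
        assert fp.V_E == pytest.approx(fps[0].V_E, abs=1e-8)
        assert fp.Q_E == pytest.approx(fps[0].Q_E, rel=1e-8)


def test_fixed_point_approaches_balanced_limit():
    """Scaling in-degrees by k and weights by 1/sqrt(k) suppresses the leak
    term, driving the fixed-point rates to the balanced-limit solution."""
    p = default_params()
    target = np.array(mf.solve_balanced_rates(p))
    errs = []
    for k in (1.0, 64.0, 4096.0):
        f = np.sqrt(k)
        pk = p.replace(n_E=p.n_E * k, n_I=p.n_I * k, n_o=p.n_o * k,
                       J_EO=p.J_EO / f, J_IO=p.J_IO / f, J_EE=p.J_EE / f,
                       J_IE=p.J_IE / f, J_EI=p.J_EI / f, J_II=p.J_II / f)
        fp = mf.solve_fixed_point(pk)
        errs.append(abs(fp.Q_E - target[0]) / target[0])
    assert errs[2] < errs[1] < errs[0]
    assert errs[2] < 0.02


def _field_rhs(params, x):
    """Independent re-statement of the deterministic 6-D vector field."""
    V_E, V_I, PE, dPE, PI, dPI = x
    Q_E = mf.transfer_rate(V_E, params.sigma_E, params.V_th)
    Q_I = mf.transfer_rate(V_I, params.sigma_I, params.V_th)
    return np.array([
        (params.V_rest_E - V_E) / params.tau_m_E + params.J_EO * params.n_o * params.Q_o
        + params.J_EE * PE + params.J_EI * PI,
        (params.V_rest_I - V_I) / params.tau_m_I + params.J_IO * params.n_o * params.Q_o
        + params.J_IE * PE + params.J_II * PI,
        dPE,
        (params.n_E * Q_E - PE - (params.tau_d_E + params.tau_r) * dPE)
        / (params.tau_d_E * params.tau_r),
        dPI,
        (params.n_I * Q_I - PI - (params.tau_d_I + params.tau_r) * dPI)
        / (params.tau_d_I * params.tau_r)])


def test_jacobian_structure_and_finite_differences():
    p = default_params(tau_d_I=3.0)
    fp = mf.solve_fixed_point(p)
    J = mf.jacobian(p, fp)
    # rows 3 and 5 (1-based) are pure shift rows
    assert np.array_equal(J[2], [0, 0, 0, 1, 0, 0])
    assert np.array_equal(J[4], [0, 0, 0, 0, 0, 1])
    x0 = np.array([fp.V_E, fp.V_I, p.n_E * fp.Q_E, 0.0, p.n_I * fp.Q_I, 0.0])
    num = np.empty((6, 6))
    h = 1e-6
    for k in range(6):
        e = np.zeros(6)
        e[k] = h
        num[:, k] = (_field_rhs(p, x0 + e) - _field_rhs(p, x0 - e)) / (2 * h)
    scale = np.abs(J).max()
    assert np.max(np.abs(J - num)) / scale < 1e-6


def test_jacobian_consistent_with_integrator_drift():
    """One noiseless Euler-Maruyama step recovers the drift exactly, so
    finite differences of the integrator map match the analytic Jacobian."""
    p = default_params(tau_d_I=2.0)
    fp = mf.solve_fixed_point(p)
    x0 = np.array([fp.V_E, fp.V_I, p.n_E * fp.Q_E, 0.0, p.n_I * fp.Q_I, 0.0])
    dt = 1e-3

    def drift(x):
        _, X, _ = mf.integrate_field(p, duration=dt, dt=dt, noise=False,
                                     x0=x, sample_dt=dt)
        return (X[0] - x) / dt

    J = mf.jacobian(p, fp)
    h = 1e-6
    num = np.empty((6, 6))
    for k in range(6):
        e = np.zeros(6)
        e[k] = h
        num[:, k] = (drift(x0 + e) - drift(x0 - e)) / (2 * h)
    assert np.max(np.abs(J - num)) / np.abs(J).max() < 1e-5


def test_fast_inhibition_fixed_point_is_stable_focus():
    p = default_params(tau_d_I=1.0)
    fp = mf.solve_fixed_point(p)
    assert fp.stable
    dom = fp.eigenvalues[np.argmax(fp.eigenvalues.real)]
    assert abs(dom.imag) > 0


# ---------------------------------------------------------------- Hopf scan

def test_hopf_scan_finds_crossing_and_continuous_frequency():
    p = default_params()
    res = mf.hopf_scan(p, np.arange(1.0, 4.51, 0.05))
    assert res.bifurcation_found
    assert 2.0 < res.tau_dI_critical < 4.0
    # frequency of the tracked pair varies continuously (no branch jumps)
    assert np.max(np.abs(np.diff(res.freq_hz))) < 15.0
    # Re lambda changes sign exactly where reported
    below = res.tau_dI_grid < res.tau_dI_critical
    assert np.all(res.re_lambda[below] < 0)


def test_instantaneous_synapse_limit_has_no_crossing():
    """With synaptic filtering removed (tau_r, tau_d -> 0) the system
    reduces to the 2-D form, which cannot lose stability on the scan."""
    p = default_params(tau_r=0.005, tau_d_E=0.02)
    res = mf.hopf_scan(p, np.array([0.02, 0.03, 0.04, 0.05]))
    assert not res.bifurcation_found
    # analytic 2-D reduction: both eigenvalues have negative real part
    fp = mf.solve_fixed_point(p)
    dQE = mf.transfer_rate_derivative(fp.V_E, p.sigma_E, p.V_th)
    dQI = mf.transfer_rate_derivative(fp.V_I, p.sigma_I, p.V_th)
    J2 = np.array([[-1 / p.tau_m_E + p.J_EE * p.n_E * dQE, p.J_EI * p.n_I * dQI],
                   [p.J_IE * p.n_E * dQE, -1 / p.tau_m_I + p.J_II * p.n_I * dQI]])
    assert np.all(np.linalg.eigvals(J2).real < 0)


# ---------------------------------------------------------------- field SDE

def test_field_converges_to_fixed_point_below_bifurcation():
    p = default_params(tau_d_I=2.0)
    fp = mf.solve_fixed_point(p)
    x0 = np.array([fp.V_E + 2.0, fp.V_I - 2.0, p.n_E * fp.Q_E, 0.0,
                   p.n_I * fp.Q_I, 0.0])
    _, X, _ = mf.integrate_field(p, duration=400.0, dt=0.01, noise=False, x0=x0)
    assert X[-1, 0] == pytest.approx(fp.V_E, abs=1e-4)
    assert X[-1, 1] == pytest.approx(fp.V_I, abs=1e-4)


def test_field_oscillates_above_bifurcation_with_sqrt_amplitude_growth():
    p = default_params()
    res = mf.hopf_scan(p, np.arange(2.5, 4.51, 0.1))
    tc = res.tau_dI_critical

    def amplitude(td):
        q = p.replace(tau_d_I=td)
        fp = mf.solve_fixed_point(q)
        x0 = np.array([fp.V_E + 0.5, fp.V_I, q.n_E * fp.Q_E, 0.0,
                       q.n_I * fp.Q_I, 0.0])
        _, X, _ = mf.integrate_field(q, duration=1500.0, dt=0.01, noise=False,
                                     x0=x0)
        tail = X[-300:, 0]
        return (tail.max() - tail.min()) / 2

    a1 = amplitude(tc + 0.15)
    a2 = amplitude(tc + 0.6)
    assert a1 > 1e-3 and a2 > a1
    # supercritical normal form: amplitude ~ sqrt(tau - tau_c)
    assert a2 / a1 == pytest.approx(np.sqrt(0.6 / 0.15), rel=0.4)


def test_field_population_ff_deterministic_is_tiny():
    p = default_params(tau_d_I=1.0)
    ff = mf.field_population_ff(p, duration=3000.0, seed=0, dt=0.02)
    ff_nonoise = None
    # noise off, equilibrated: counts constant -> FF ~ 0
    fp = mf.solve_fixed_point(p)
    x0 = np.array([fp.V_E, fp.V_I, p.n_E * fp.Q_E, 0.0, p.n_I * fp.Q_I, 0.0])
    t, X, Q = mf.integrate_field(p, duration=2000.0, dt=0.02, noise=False, x0=x0)
    counts = p.N_E * Q[t > 500, 0] * 50.0
    assert counts.var() / counts.mean() < 1e-6
    assert ff > counts.var() / counts.mean()


def test_field_population_ff_increases_across_transition():
    p = default_params()
    ff1 = mf.field_population_ff(p.replace(tau_d_I=1.0), duration=4000.0, seed=1, dt=0.02)
    ff4 = mf.field_population_ff(p.replace(tau_d_I=4.0), duration=4000.0, seed=1, dt=0.02)
    assert ff4 > ff1
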