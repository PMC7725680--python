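"""Numba-compiled integration loop for the spiking network.

The bi-exponential synaptic filter F(t) = [exp(-t/tau_d) - exp(-t/tau_r)]
/ (tau_d - tau_r) is the impulse response of a second-order linear ODE, so
per neuron the total filtered input from one presynaptic class is carried
as two exponential accumulators (a, b) with decay constants tau_d and
tau_r that are advanced *exactly* between step boundaries; an incoming
spike increments both by exp(-s/tau) where s is the time from the
(interpolated) crossing to the step boundary, so delivery is sub-step
accurate.  Weights are applied at read-out.  The cost is O(N) per step
plus O(out-degree) per emitted spike.

Membrane potentials are advanced with Heun's method (second order on
smooth segments).  Threshold crossings are located by linear
interpolation inside the step; the membrane is then clamped at V_reset
(synaptic integration halted) until exactly t_spike + t_ref, resuming
with a partial Heun step in the release step, which keeps single-neuron
inter-spike intervals accurate to O(dt^2).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1      # spike buffer exhausted
STATUS_UNSTABLE = 2      # |V| exceeded 1e3 mV


@njit(cache=True)
def integrate(V, t_ref, tau_m, v_rest,
              v_th, v_reset, i_const,
              cO, cE, cI,
              dec_dE, dec_dI, dec_r,
              tau_d_E, tau_d_I, tau_syn_r,
              indptr, indices, N_E,
              lam_ext, dt, n_steps,
              rec_idx, rec_every, rec_out,
              spike_t, spike_i, seed):
    """Advance the network for n_steps of size dt.

    Returns (status, n_spikes).  rec_out is filled with voltage samples of
    the neurons in rec_idx every rec_every steps (sample k at
    t = (k+1)*rec_every*dt, post-reset convention)."""
    np.random.seed(seed)
    N = V.size
    aO = np.zeros(N)
    bO = np.zeros(N)
    aE = np.zeros(N)
    bE = np.zeros(N)
    aI = np.zeros(N)
    bI = np.zeros(N)
    release = np.full(N, -1.0)   # refractory release time; < t means free
    spikers = np.empty(N, dtype=np.int64)
    spike_frac = np.empty(N)
    n_sp = 0
    max_sp = spike_t.size
    n_rec = 0

    for step in range(n_steps):
        t = step * dt
        t1 = t + dt
        n_spikers = 0
        for i in range(N):
            # currents at the step start and (exactly decayed) step end;
            # boundary arrivals contribute F(0)=0, so injection happens
            # after the end-of-step read-out.
            I0 = cO[i] * (aO[i] - bO[i]) + cE[i] * (aE[i] - bE[i]) \
                + cI[i] * (aI[i] - bI[i]) + i_const
            a1O = aO[i] * dec_dE
            b1O = bO[i] * dec_r
            a1E = aE[i] * dec_dE
            b1E = bE[i] * dec_r
            a1I = aI[i] * dec_dI
            b1I = bI[i] * dec_r
            I1 = cO[i] * (a1O - b1O) + cE[i] * (a1E - b1E) \
                + cI[i] * (a1I - b1I) + i_const
            aO[i] = a1O
            bO[i] = b1O
            aE[i] = a1E
            bE[i] = b1E
            aI[i] = a1I
            bI[i] = b1I

            if release[i] >= t1:
                V[i] = v_reset            # fully refractory step
                continue
            if release[i] > t:
                # released mid-step: partial Heun step over h = t1 - release
                h = t1 - release[i]
                eaE = np.exp(h / tau_d_E)
                eaI = np.exp(h / tau_d_I)
                er = np.exp(h / tau_syn_r)
                Ir = cO[i] * (a1O * eaE - b1O * er) \
                    + cE[i] * (a1E * eaE - b1E * er) \
                    + cI[i] * (a1I * eaI - b1I * er) + i_const
                v0 = v_reset
                t_base = release[i]
                k1 = (v_rest[i] - v0) / tau_m[i] + Ir
            else:
                h = dt
                v0 = V[i]
                t_base = t
                k1 = (v_rest[i] - v0) / tau_m[i] + I0
            v_pred = v0 + h * k1
            k2 = (v_rest[i] - v_pred) / tau_m[i] + I1
            v_new = v0 + 0.5 * h * (k1 + k2)
            if v_new >= v_th:
                # sub-step crossing time by linear interpolation
                frac = (v_th - v0) / (v_new - v0)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                t_sp = t_base + frac * h
                if n_sp >= max_sp:
                    return STATUS_OVERFLOW, n_sp
                spike_t[n_sp] = t_sp
                spike_i[n_sp] = i
                n_sp += 1
                spikers[n_spikers] = i
                spike_frac[n_spikers] = (t1 - t_sp) / dt
                n_spikers += 1
                V[i] = v_reset
                release[i] = t_sp + t_ref[i]
            else:
                V[i] = v_new
                if v_new > 1e3 or v_new < -1e3:
                    return STATUS_UNSTABLE, n_sp

        # external Poisson drive: superposition of n_o sources at Q_o is a
        # single Poisson process of rate n_o*Q_o per neuron
        if lam_ext > 0.0:
            for i in range(N):
                k = np.random.poisson(lam_ext)
                if k > 0:
                    aO[i] += k
                    bO[i] += k

        # recurrent propagation of this step's spikes: each impulse is
        # injected with the filter already advanced from the interpolated
        # crossing time to the step boundary
        for s in range(n_spikers):
            j = spikers[s]
            rem = spike_frac[s] * dt
            if j < N_E:
                wa = np.exp(-rem / tau_d_E)
                wb = np.exp(-rem / tau_syn_r)
                for q in range(indptr[j], indptr[j + 1]):
                    tgt = indices[q]
                    aE[tgt] += wa
                    bE[tgt] += wb
            else:
                wa = np.exp(-rem / tau_d_I)
                wb = np.exp(-rem / tau_syn_r)
                for q in range(indptr[j], indptr[j + 1]):
                    tgt = indices[q]
                    aI[tgt] += wa
                    bI[tgt] += wb

        # voltage sampling (post-reset convention: after the update above)
        if rec_every > 0 and (step + 1) % rec_every == 0:
            if n_rec < rec_out.shape[1]:
                for r in range(rec_idx.size):
                    rec_out[r, n_rec] = V[rec_idx[r]]
                n_rec += 1

    return STATUS_OK, n_sp
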