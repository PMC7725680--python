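# Methods

This note records the model conventions, numerical choices and known
limitations of the package.  Units are mV and ms everywhere internally;
rates are per-ms internally and Hz at public interfaces.

## Network model and integration scheme

The simulator integrates the current-based leaky integrate-and-fire E–I
network with bi-exponential synaptic filtering.  Because the filter
F(t) = [e^(−t/τ_d) − e^(−t/τ_r)]/(τ_d − τ_r) is the impulse response of
(τ_d d/dt + 1)(τ_r d/dt + 1)x = δ(t), each neuron carries two exponential
accumulators per presynaptic class (recurrent E, recurrent I, external)
that are advanced *exactly* between step boundaries; synaptic weights are
applied at read-out.  The cost is O(N) per time step plus O(out-degree)
per spike, which makes 16-s runs of the N = 10⁴ reference network a
few-minute desk computation.

Membrane potentials advance with Heun's method (second order on smooth
segments) at dt = 0.05 ms.  Threshold crossings are located by linear
interpolation inside the step and recorded at the interpolated time;
synaptic delivery applies the filter decay from the crossing time to the
step boundary, so delivery is also sub-step accurate.  Two reasons drove
the interpolated-time convention over recording spikes at step
boundaries:

1. single-neuron periods then match the closed-form LIF solution
   t_ref + τ ln((V∞−V_reset)/(V∞−V_th)) to ~10⁻⁵ ms at the default dt
   (the suite asserts 10⁻³), with clean second-order convergence;
2. the avalanche pipeline bins population spikes at the merged-train
   mean ISI T_m, which at the reference rates (~0.02–0.06 ms) is at or
   below dt — boundary-quantized spike times would collapse every
   avalanche to duration 1.

During the refractory period (2 ms E, 1 ms I, counted from the
interpolated spike time) the membrane is clamped at V_reset and synaptic
integration of the voltage is halted, while the neuron's synaptic filter
states keep evolving so input arriving during refractoriness is not
lost.  The neuron resumes with a partial Heun step in the step containing
its release time.  Whether the leak acts during refractoriness is a
convention; clamping was chosen and is easy to flag for sensitivity
studies.

External drive: the superposition of n_o independent Poisson sources at
rate Q_o is simulated as one Poisson process of rate n_o·Q_o per neuron
(statistically identical), each event filtered through the excitatory
kernel.  Connectivity is directed Erdős–Rényi on ordered pairs without
self-edges; "neighbors" are presynaptic.  n_o is the fixed value p·N_E
rather than binomially distributed, matching the mean recurrent
excitatory in-degree.

Voltage is recorded at 1-ms samples (post-reset convention, all samples
≤ V_th) for an evenly spaced per-population subsample of 2000 neurons by
default; pooled-moment and coherence estimators are unbiased under
neuron subsampling, and full recording is available via `record_n=None`.

## Mean-field calibration and bifurcation analysis

The field equations close the population rate through the logistic
transfer Q_α(V) = 1/(1+exp((V_th−V)π/(√3σ_α))) — the suprathreshold
fraction of a Gaussian voltage cloud after the erf→tanh approximation.
σ_α absorbs everything the first-order closure neglects (higher-order
statistics, input correlations, refractoriness), so its value is an
empirical calibration, not a prediction.  Two calibrations are provided:

* **measured** (the default protocol): run one asynchronous-state
  simulation (τ_d^I = 1 ms), average ⟨V⟩ and the rate per population over
  the post-transient window, invert the transfer function.  At the
  reference parameters this gives σ ≈ (7.3, 8.6) mV and a Hopf crossing
  at τ_d^I ≈ 3.5 ms, consistent with where the simulated network's own
  synchrony indices (population-rate CV, PSD peak emergence) rise.
* **closed-form** (`sigma_diffusion`): the Ornstein–Uhlenbeck stationary
  SD σ = J√(n_o Q_o τ_m/2) of a leaky integrator driven by the external
  noise alone, ≈ (4.0, 4.6) mV, giving a crossing at ≈ 2.8 ms.  A
  `halved=False` switch drops the 1/2 factor (≈ (5.7, 6.4) mV, crossing
  ≈ 3.1 ms) because the prefactor convention differs between common
  statements of this formula.

The critical τ_d^I is therefore calibration-dependent within roughly
2.8–3.5 ms; the package's acceptance pipeline uses the measured protocol
and anchors "critical state" analyses to the crossing it computes.

The fixed point is solved as a 2-D root problem in (V_E, V_I) (scipy
hybr with multistart from rest and from the balanced-limit rates mapped
through the inverse transfer; residual < 10⁻¹⁰).  It is invariant to
τ_r, τ_d by construction — the filter is normalized — which the suite
asserts.  The 6×6 Jacobian is analytic and is checked against central
finite differences of the integrator's own drift.  The Hopf scan tracks
the dominant eigenvalue pair by eigenvector overlap, seeded at the grid
point where the maximal real part peaks (where the pair is unambiguous)
and swept outward, which avoids branch jumps where eigenvalue real parts
cross; the crossing is refined by bisection.  The stochastic field
equations are integrated by Euler–Maruyama at dt = 0.01 ms with noise
amplitude J_αO√(n_o Q_o/N_α) entering only the voltage rows; the
population Fano factor uses deterministic counts N_α·Q_α·Δt in 50-ms
windows.

## Statistics conventions

Count series use half-open bins; the square kernel is a trailing moving
average.  CV of ISI excludes neurons with fewer than 3 spikes.  Pairwise
correlation uses square-filtered (T = 50 ms) 1-ms count series; when the
population exceeds 150 neurons, 150 are sampled uniformly (seeded) and
all of their ≈10⁴ pairs are averaged — an unbiased estimate of the
all-pairs average that avoids materializing 8000 filtered series.  PSDs
are Welch periodograms (1-s Hann segments, 50% overlap, mean detrended);
the decay exponent β is a least-squares log-log slope over
[1.5×peak, 1000 Hz] by default (explicitly configurable, and an explicit
range should be given for spectra without a genuine peak).  Voltage
moments are computed on the pooled neurons × samples distribution of the
excitatory population in the headline analyses.

## Avalanche battery

The bin width is the mean ISI of the merged population spike train
(T_m); avalanches are maximal runs of non-empty bins, and runs touching
the record boundary are discarded.  The distance D uses an 80-bin
logarithmic histogram (the fit lives in log-log coordinates; a linear
option exists), empty bins excluded.

The doubly truncated discrete power-law MLE normalizes by Hurwitz-zeta
differences and tests goodness with the discrete KS statistic
(right-continuous CDFs compared at the support atoms) against ≥100
surrogate datasets drawn from the fitted law and refitted.  Candidate
truncation bounds are the observed unique values subsampled to ≤50 per
bound; ranges narrower than one third of the observed log range are
never acceptable and are skipped; the widest range with p > 0.1 wins.
Two shortcuts keep this fast without changing decisions: ranges whose
KS·√n exceeds 2.5 (far beyond the refitted-null scale ~n^(−1/2)) are
scored p = 0 without surrogates, and the surrogate loop stops early once
acceptance or rejection at the 0.1 threshold is already decided (with a
30-surrogate futility checkpoint).  The ⟨S⟩(T) exponent is a weighted
least-squares slope over per-duration mean sizes within the duration
fit's truncated range, weights = avalanche counts.

At the reference critical state this battery accepts both tails with
τ ≈ 1.9, α ≈ 2.1, 1/σνz ≈ 1.3 and scaling error |(α−1)/(τ−1) − 1/σνz|
≈ 0.005–0.06; the independent-Poisson null is rejected outright.

## Macroscopic Langevin avalanches

The normal-form walk dX = (aX − X³ + h)dt + √(max(X,0))dW from
X(0) = ε is integrated by Euler–Maruyama (default ε = 10⁻², dt = 10⁻⁴;
the guard dt ≤ ε/10 resolves the ~ε absorption time scale); within-step
negative excursions are absorbed, sizes are trapezoid areas.

Two first-passage densities are provided.  `fpt_density` evaluates the
quoted closed form (2ε)^{1−4h}/Γ(½−h) · t^{4h−3/2} · e^{−2ε²/t}; note
that as stated it is not unit-normalized (its mass at h = 0 is √2) and
its h = 0 tail exponent −3/2 is not what the simulated walk does
asymptotically.  `fpt_density_exact` gives the exact law of the
small-X walk: u = 2√X maps it onto a Bessel process of dimension 4h, so
P(T=t) = (2ε)^{1−2h}/Γ(1−2h) · t^{2h−2} · e^{−2ε/t}, unit-normalized,
with survival 1 − e^{−2ε/t} at h = 0 — which the simulation matches to
KS < 0.05.  The asymptotic tail exponent at h = 0 is therefore −2; the
often-quoted −3/2 is the *effective* slope over the decade immediately
above the density peak at t ≈ ε, where both forms agree, and the tests
measure it in exactly that declared window.  ⟨S⟩(T) ∼ T² holds for the
unbiased walk in either reading.

## Up-states and surrogates

Up-states are supra-threshold runs (≥1 s) of the population rate binned
at 10 ms and smoothed with a 100-ms square kernel, threshold 30% of the
filtered series' maximum (switchable to the raw maximum); no gap-merging
is applied.  ISI shuffling permutes each neuron's ISIs within each
up-state with the first spike anchored, preserving per-neuron counts,
segment-local spans and ISI multisets — it destroys avalanche temporal
structure, and the suite shows planted wide-range power laws do not
survive it.

## Synthetic fixtures: what they do and do not emulate

The fixture generators provide rasters with known ground truth:
homogeneous Poisson (asynchronous null), sinusoidally thinned Poisson
(sparse synchrony with a known PSD peak), telegraph up-down modulation
at a 0.1-Hz cycle with lognormal (σ_log = 1) per-neuron rate
heterogeneity emulating the broad rate distributions of cultured-slice
recordings, and count series with planted truncated power-law avalanches
(spikes spread over durations by the S ∼ T² allocation).  They emulate
first-order statistical structure only: no spatial electrode geometry,
no refractoriness, no genuine recurrent dynamics.  Tests passing on
fixtures therefore certify the estimators, not the biology; the network
simulator provides the mechanistic data.

## Problem sizes used in the checks

The automated checks simulate the full N = 10⁴ network with 3–5-s
post-transient analysis windows (the asserted quantities — rates,
voltage moments, CV, spectral exponents, avalanche exponents —
equilibrate well within that), and the acceptance script uses 5-s
windows; reduced-size examples rescale weights by √(10⁴/N).  The
exponent-relation check across Q_o ∈ {4…8} Hz runs five such critical
states.

## Known limitations

* Transmission delays are carried in the configuration but must be zero;
  the delay-differential stability analysis is out of scope.
* Conductance-based dynamics, plasticity and structured topologies are
  out of scope.
* The mean-field σ_α calibration is the dominant source of uncertainty
  in the predicted critical τ_d^I (≈ 2.8–3.5 ms across defensible
  calibrations, see above); all downstream "critical state" numbers are
  anchored to the computed crossing.
* The κ-index is deliberately not implemented; the distance D replaces it.
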