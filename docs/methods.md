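# Methods

`cardiouq` implements two complementary uncertainty-quantification workflows
for cardiac action-potential (AP) models: Bayesian inference of maximal
conductances from voltage traces, and Gaussian-process (GP) emulation of an
AP model for sensitivity analysis and uncertainty propagation. This note
records the models, statistical procedures, numerical choices and known
limitations.

## Cell models

Four ventricular AP models are transcribed from their primary publications
and exposed through a common contract (`rhs(y, t, theta, Ko, stim)` in mV,
ms, mM, pA/pF):

| model | states | conductance parameters |
|---|---|---|
| `beeler_reuter_1977` | 8 | `G_Na`, `G_s`, `G_x1`, `G_K1` |
| `luo_rudy_1991` | 8 | 6 (`G_Na` ... `G_b`) |
| `tentusscher_2004` (epi) | 17 | 12 (`G_Na` ... `k_NaCa`) |
| `tentusscher_2006_epi` | 19 | 12 + `tau_f_multiplier` |

For Beeler-Reuter the four scalable parameters are the sodium conductance,
the slow-inward conductance and the magnitudes of the time-dependent and
time-independent potassium currents (the 0.003 mS/cm2 background sodium
conductance stays fixed). The TP06 `tau_f_multiplier` scales the voltage
inactivation time constant of the L-type calcium current's f gate.

Each transcription is validated in the test suite against published
behaviour: resting potential, AP morphology (the epicardial
spike-notch-dome), APD90 at 1 Hz (TP06 beat 20: 305.4 ms, against the
306.7 ms centre value the emulator study reproduces), the < 0.5 ms
beat-19/beat-20 APD difference under 20-beat pacing, and the consistency of
the jitted right-hand side with an independently coded per-current
decomposition. Initial conditions: TT04 and TP06 use their published
(CellML) initial states; for BR and LR91 a quiescent steady state was
computed by long unstimulated integration at default conductances and
frozen into the source (residual derivative magnitudes < 1e-15).

Extracellular potassium is a boundary condition (`Conditions.Ko`); BR has no
[K+]o dependence, so the potassium-change protocols refuse it ("not
applicable").

## Protocols

The protocol library covers: a single 1 Hz AP in a 1000 ms window (one full
cycle, wide enough for every registered model's APD); the same with [K+]o
halved or doubled; an S1-S2 protocol (1000 ms at 1 Hz, then 1000 ms at 2 Hz,
three APs in 2000 ms, S2 stimuli at 1000 and 1500 ms); a knockout protocol
(2000 ms at 1 Hz with one conductance zeroed at 1000 ms, applied as an
instantaneous event with the integrator restarted); and long pacing (1 Hz
for a chosen duration, e.g. 10 or 20 s). Default stimulus: -52 pA/pF for
1 ms, also used for the plain-ODE models where it reliably elicits an AP;
absolute-current stimuli can be converted via a cell capacitance for
experimental protocols. Drug action is pore block: each affected conductance
is scaled by 1/(1 + (C/IC50)^h), Hill coefficient h = 1 by default since
only IC50s are specified; `pic50_to_ic50` converts pIC50 to uM.

## Simulation

LSODA (adaptive stiff/non-stiff multistep, via `scipy.integrate.odeint`)
with rtol 1e-6 / atol 1e-8, right-hand sides compiled with numba.
Integration restarts at every stimulus edge and protocol event so
discontinuities are exact; the maximum internal step is capped at the
stimulus duration inside stimulus windows. Output is sampled by the solver's
dense interpolation at exact multiples of the 0.2 ms sample interval (not at
solver steps). Halving the tolerances moves every TP06 biomarker by less
than 0.1 ms / 0.1 mV (tested). Synthetic traces are bit-for-bit reproducible
given (model, parameters, protocol, noise sd, seed).

Synthetic data emulate an ideal recording of a known cell: simulate at the
published conductances after 100 pre-pacing beats at the protocol's first
rate, sample at 0.2 ms, and add iid Normal noise of sd 0.25 mV (the noise
level of a repolarised canine AP recording at rest). What synthetic data do
not contain: structural model error, baseline drift, correlated noise,
stimulus artifacts, or beat-to-beat physiological variability - so passing
recovery tests bounds estimator quality under a correct model, not
performance on real recordings.

## Biomarkers

Six per-beat descriptors: max dVm/dt, max Vm, dome Vm, APD90, resting Vm,
APD50. Conventions, applied identically to simulator and emulator targets:
resting Vm is the sample immediately before the stimulus; the upstroke
instant is the time of maximum central-difference derivative; APD_x runs
from the upstroke instant to the interpolated crossing of
V_peak - (x/100)(V_peak - V_rest); dome Vm is the post-notch plateau
maximum (or the plateau maximum 30 ms after the upstroke when no notch
exists). A beat that never crosses a repolarisation threshold leaves that
APD `None` - never a substitute number.

The max-dVm/dt search includes the stimulus window by default. Under
current-clamp pacing the sodium upstroke happens *during* the 1 ms stimulus;
excluding the window (an option intended for recordings with large electrode
artifacts) would report the plateau slope (~33 mV/ms for TP06) instead of
the upstroke velocity (~200 mV/ms on the 0.2 ms grid). Note the 0.2 ms grid
itself blurs the upstroke: at 0.05 ms sampling TP06's maximum upstroke
velocity reads ~357 mV/ms. All emulator results use the package-wide 0.2 ms
convention; this resolution dependence is the main caveat when comparing
upstroke-velocity statistics across implementations.

## Inference (case study 1)

Observation model: observed trace = simulated trace + iid Normal(0, sigma^2)
noise, so the log-likelihood is the sum of per-sample Normal log-densities.
Likelihood simulations start from the same initial state that generated the
data, so the generating parameters attain the exact likelihood optimum.
Priors are independent uniforms: (0.1x, 10x) the published value per
conductance, and (0, 25] mV for sigma (unstated in the source methodology;
generous but proper).

The sampler is started from the best point found by CMA-ES (own
implementation of the standard rank-mu update strategy; population
4 + 3 ln d, 3 restarts from independent prior draws, box handling by
clipping). The search runs in log-parameter coordinates: conductances are
scale parameters with a 100-fold prior range, and on the linear scale the
published values sit at 9% of the box, where every restart collapsed into a
"scaled-conductance" local optimum thousands of nats worse than the truth.
In log coordinates all restarts reach the global basin. The objective is
unchanged and MCMC still samples the linear scale, matching the uniform
prior.

MCMC is adaptive-covariance Metropolis (Haario-type): Normal proposals with
covariance lambda^2 Sigma; after a 200-iteration warm-up the empirical
covariance and the global scale adapt with decaying rate (t - 200)^-0.6,
the scale steering acceptance to ~0.25. Proposals outside the prior box are
rejected. Chains are post-processed by discarding the first quarter and
(for storage) thinning by 10; the identifiability metric

    M_i = (1/N) sum_t |theta_hat_i - theta_{t,i}| / theta_hat_i

is computed on the post-burn-in, unthinned chain, and a parameter counts as
successfully inferred when M_i < 0.05. Credible intervals are nearest-rank
empirical central intervals (discard the outermost 2.5% each side).
Study-grade chains default to 100,000 iterations; the test suite and the
acceptance script run 20,000-iteration chains (and 800-3,000-iteration
posterior probes for the 17-state model), which this problem's sharply
peaked posteriors resolve well - the Beeler-Reuter single-AP study yields
every M_i < 0.01 at 20,000 iterations.

## Emulation (case study 2)

Inputs are the 13 TP06 parameters, each over (0.5x, 1.5x) its published
value, affinely normalised to [0,1] (0.5 = published value). Designs are
Latin hypercube samples (via `scipy.stats.qmc`); each design run is 20 beats
at 1000 ms cycle length with -52 pA/pF x 1 ms stimuli from the published
initial conditions, and the outputs are the six biomarkers of beat 20.
Non-repolarising runs would be excluded with a warning (none occur over
these ranges), but note that extreme corners of the box - e.g. L-type
calcium conductance at its minimum together with a fast tau_f - approach
their pacing steady state more slowly, and an occasional design cell can
still drift slightly more than 0.5 ms/beat in APD90 at beat 20.

One GP per output: squared-exponential kernel with per-input length-scales,
linear mean h(x) = [1, x], GLS mean coefficients, and process variance by
concentrated maximum likelihood over the log length-scales (L-BFGS-B,
5 starts, fixed seed). A relative noise nugget is estimated jointly rather
than fixed: biomarkers extracted from a sampled trace carry grid jitter
(where the upstroke lands relative to the 0.2 ms grid), which is observation
noise from the emulator's point of view. An alternative leave-one-out
cross-validated objective (Dubrule's universal-kriging form) is available
(`objective="loo"`).

For independent Gaussian inputs x ~ N(b, diag B), every reported quantity is
an analytic Gaussian integral of the fitted surface: the propagated output
mean and variance use closed-form kernel moments E[r_i], E[x r_i],
E[r_i r_j]; mean-effect curves are the same integrals with one input's
variance set to zero; and the main-effect index
S_i = Var(E[Y|X_i]) / Var(Y) adds a 1-D Gauss-Hermite quadrature (41 nodes)
over the conditioned input. All are cross-checked against Monte-Carlo
oracles in the tests. Input measures are used un-truncated even though the
design lives on [0,1]; with input sd <= 0.2 the mass outside the box is
<= 1.3% and covered by the Monte-Carlo tolerance. Propagation reports the
input-driven variance (variance of the posterior-mean surface) and the
expected predictive variance ("code uncertainty") separately; headline sd
values are input-driven.

Validation computes the joint Mahalanobis distance of 10 held-out runs under
the emulator's predictive distribution (noise included), with the central
95% of chi-squared(m) as the pass band. Honest finding: with this simulator,
50-point emulators have accurate predictive *means* (test RMSE a few percent
of the output range) but optimistic predictive *variances* for several
outputs, and fail the strict joint test - 50 points in 13 dimensions cannot
see localised interaction structure, and neither the ML nor the LOO fit
fully repairs that. The validation report makes this visible rather than
papering over it.

## Numerical and degenerate-input choices

- Protocol events and stimulus edges are integration breakpoints; event
  conductance factors always scale the *base* parameter vector.
- I_CaL driving-force singularities (V = 0 for TT04, V = 15 mV for TP06)
  and the rate-function singularities (e.g. alpha_m) use their analytic
  limits within 1e-6 mV of the singular voltage.
- A flat trace yields resting Vm only; a non-repolarising beat yields
  `None` APDs; `mape_metric` raises for a zero true value.
- Propagation with all input variances zero degenerates exactly to the
  emulator prediction at the mean input.
- Credible intervals require >= 40 samples; GP fits require >= d + 2 design
  points; covariance factorisations escalate jitter before failing.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: 20,000
MCMC iterations for the 8-state Beeler-Reuter study; 3,000 / 800 iteration
posterior probes for the TT04 single-AP / 20 s protocol comparison
(started at the generating parameters, probing posterior width rather than
optimiser behaviour); 50 design + 10 test TP06 runs. Study-grade settings
(100,000 iterations, CMA-ES initialisation everywhere) are the library
defaults.

## Known limitations

- Single-cell only; no tissue electrophysiology, no stochastic gating.
- The emulator assumes a smooth response over the input box; regimes with
  alternans or loss of capture (outside these ranges at 1 Hz) would break
  the smoothness assumption.
- O'Hara 2011 and Davies 2012 (canine) are interface-level plug-ins only
  (`register_model`); their equations are not transcribed, so the canine
  experimental workflow runs only once such a model is registered.
- M_i requires the generating parameters, so identifiability studies are
  synthetic-mode only; for experimental traces the CLI reports M against
  the published values, which is a discrepancy measure, not an error.
- Upstroke-velocity statistics depend on the sampling convention (see
  Biomarkers); APD-based statistics are insensitive to it.
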