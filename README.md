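# cardiouq

Uncertainty quantification for cardiac action-potential (AP) models.

Cardiac electrophysiology models describe the membrane voltage of a myocyte
through a stiff ODE system whose most influential parameters are the maximal
conductances/densities **θ** of its ion currents, pumps and exchangers.
Those conductances are not directly measurable and vary between cells and
even between beats, yet models are usually run with single fixed values.
`cardiouq` replaces point values with probability distributions, for
modellers and safety-pharmacology researchers who need to know *how well a
voltage recording constrains each conductance* and *how conductance
uncertainty propagates into predicted AP behaviour*.

Two workflows:

**1. Bayesian conductance inference.** For a voltage trace sampled every
0.2 ms with iid Gaussian noise, the log-likelihood of conductances θ and
noise sd σ is

    log p(data | θ, σ) = Σ_i [ -½ log(2πσ²) - (V_i^sim(θ) - V_i^obs)² / (2σ²) ]

with uniform priors on (0.1·θ̂, 10·θ̂) per conductance (θ̂ = published value)
and on (0, 25] mV for σ. CMA-ES locates the likelihood peak; an
adaptive-covariance Metropolis chain samples the posterior π(θ, σ | data).
Identifiability is scored per parameter by the mean absolute percentage
error over the post-burn-in chain,

    M_i = (1/N) Σ_t |θ̂_i − θ_{t,i}| / θ̂_i ,   success ⇔ M_i < 0.05.

**2. Gaussian-process emulation.** For the ten Tusscher–Panfilov 2006
epicardial model (TP06), a Latin-hypercube design over the 13 inputs (each
published value ± 50%, normalised to [0, 1]) feeds one GP per AP biomarker
(max dVm/dt, max Vm, dome Vm, APD90, resting Vm, APD50 of beat 20 under
1 Hz pacing). With independent Gaussian inputs the propagated output mean
and variance, mean-effect curves, and main-effect sensitivity indices
S_i = Var(E[Y|X_i]) / Var(Y) are all computed **analytically** from the
fitted GP — no further simulator runs.

Registered models: Beeler–Reuter 1977, Luo–Rudy 1991, ten Tusscher 2004
(epi), TP06 (epi); protocols: single AP, [K+]o × 0.5 / × 2, S1–S2, current
knockout, long pacing; drug effects as IC50 conductance block.
See `docs/methods.md` for conventions, numerics and limitations.

## Worked example

Simulate one paced TP06 epicardial AP and describe its shape:

```bash
$ python examples/01_simulate_and_biomarkers.py
samples: 5001 at 0.2 ms
resting Vm :   -85.23 mV   (diastolic potential before the stimulus)
max dVm/dt :   193.77 mV/ms (upstroke velocity)
max Vm     :    36.96 mV   (spike overshoot)
dome Vm    :    23.47 mV   (plateau after the epicardial notch)
APD50      :   261.80 ms   (time to 50% repolarisation)
APD90      :   290.28 ms   (time to 90% repolarisation)
```

The first beat from the published initial state is ~15 ms shorter than the
1 Hz steady state (APD90 ≈ 306 ms by beat 20) — pre-pace before comparing
with steady-pacing data. Model a 10 µM moxifloxacin exposure as conductance
block and re-simulate:

```bash
$ python examples/04_drug_block.py
I_Kr: IC50   29.0 uM -> remaining fraction 0.744
I_Na: IC50  206.7 uM -> remaining fraction 0.954
I_Ks: IC50  158.5 uM -> remaining fraction 0.941
I_CaL: IC50  158.5 uM -> remaining fraction 0.941

APD90 control:  307.1 ms
APD90 at 10 uM:  317.5 ms  (I_Kr block prolongs repolarisation by +10.4 ms)
```

`examples/02_infer_conductances.py` runs a reduced conductance-recovery
study (all four Beeler–Reuter conductances and σ recovered with M_i < 0.05
from one noisy AP) and `examples/03_emulator_sensitivity.py` builds a small
emulator and prints which inputs drive upstroke velocity (G_Na) and APD90
(G_Kr, G_Ks, G_CaL, τ_f). A thin CLI mirrors the library:
`cardiouq simulate|fit|study|design|emulate|sensitivity|propagate --help`.

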