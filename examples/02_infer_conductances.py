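"""Infer maximal conductances from a noisy synthetic action potential.

Generates a Beeler-Reuter 1 Hz AP, adds Normal(0, 0.25 mV) noise, 'forgets'
the conductances, and recovers them: CMA-ES finds the likelihood peak, an
adaptive Metropolis chain explores the posterior, and each parameter is
scored by its mean absolute percentage error M_i (success: M_i < 0.05).

A study-grade run uses 100,000 iterations; this demo uses 4,000 (~30 s).
"""

import cardiouq as cq
from cardiouq.inference import identifiability_study

model = cq.get_model("beeler_reuter_1977")
protocol = cq.make_protocol("single_ap")

report = identifiability_study(model, protocol, seed=1, n_iterations=4000)
print(report.summary())
print(f"\nMCMC acceptance rate: {report.full_chain.acceptance_rate:.2f}")
print("M_i is the mean |theta_hat - theta_t| / theta_hat over the post-burn-in chain;")
print("a parameter counts as identified when the chain stays within 5% of the truth.")
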