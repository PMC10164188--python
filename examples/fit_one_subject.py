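"""Fit the two-phase learning-curve model to a single simulated subject.

Generates one subject with known parameters, fits the EM-trained HMM, and
compares estimate with truth.  The transition day is the last day of the
fast (task-specific) learning phase; the posterior mean is the canonical
continuous estimate.
"""

import numpy as np

from phasefit import SimulationConfig, fit_em, simulate_population

subject = simulate_population(SimulationConfig(n_subjects=1, noise_sd=0.4, seed=7))[0]
fit = fit_em(subject.series, seed=0)

print(f"true:   alpha={subject.truth.alpha:.3f}  beta_ts={subject.truth.beta_ts:.3f}  "
      f"beta_cap={subject.truth.beta_cap:.4f}  transition day={subject.transition_day}")
print(f"fitted: alpha={fit.params.alpha:.3f}  beta_ts={fit.params.beta_ts:.3f}  "
      f"beta_cap={fit.params.beta_cap:.4f}  tau={fit.params.tau:.3f}  sigma={fit.params.sigma:.3f}")
print(f"transition day: posterior mean {fit.transition_day:.2f}, MAP {fit.transition_day_map} "
      f"(loglik {fit.loglik:.2f}, {fit.n_iter} EM iterations)")
print("posterior over the transition day:",
      np.array2string(fit.posterior.trans_pmf, precision=3, suppress_small=True))
# The pmf concentrates around the true switch; the accumulated task-specific
# gain at the switch is delta_ts = beta_ts / tau.
print(f"accumulated task-specific gain delta_ts = {fit.params.delta_ts:.2f} levels")
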