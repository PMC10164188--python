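"""Parameter-recovery study on a small simulated cohort.

Simulates subjects with known parameters, fits every learning curve, and
scores the estimates: bias and RMSE per parameter plus the fraction of
subjects whose estimated transition day lands within 1 and 2 days of truth.
(The full-size validation uses 1000 subjects; 100 keeps this example quick.)
"""

from phasefit import SimulationConfig
from phasefit.recovery import run_simulation_study

report = run_simulation_study(SimulationConfig(n_subjects=100, noise_sd=0.4, seed=1))

print(f"n = {report.n_subjects} subjects ({report.n_nonconverged} non-converged)")
for p in report.bias:
    print(f"  {p:>16}: bias {report.bias[p]:+.4f}   rmse {report.rmse[p]:.4f}")
for k, frac in report.fraction_within.items():
    print(f"  within {k} day(s): {100 * frac:.1f}%")
# Within-day fractions near 90%/98% show the switch is located reliably;
# the ~-0.4 day bias is the structural undershoot of the posterior-mean
# estimator when the switch-day observation lies on both phase lines.
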