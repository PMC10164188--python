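"""Clean a transfer-test panel: exclusion, k-NN imputation, standardization.

Generates a synthetic 4-task x 5-session transfer panel with a latent
capacity factor, blanks transfer cells at random, and runs the cohort
preprocessing pipeline.
"""

import numpy as np

from phasefit import exclude_incomplete, knn_impute, standardize_to_T1
from phasefit.simulate import PanelConfig, inject_missingness, simulate_transfer_panel

panel, truth = simulate_transfer_panel(PanelConfig(n_subjects=200, seed=0))
dirty = inject_missingness(panel, rate=0.1, rng=np.random.default_rng(1))
print(f"simulated {dirty.n_subjects} subjects; "
      f"{int(dirty.missing_mask().to_numpy().sum())} missing transfer cells")

kept = exclude_incomplete(dirty)          # drop subjects missing >= 6 of 15 transfer cells
print(f"after exclusion: {kept.n_subjects} subjects retained")

imputed = knn_impute(kept, k=35)          # mean of the 35 nearest neighbours per gap
print(f"after imputation: {int(imputed.missing_mask().to_numpy().sum())} missing cells")

z = standardize_to_T1(imputed)            # per task: (x - mean_T1) / sd_T1
t1 = z.scores[("Grid", 1)]
print(f"Grid T1 after standardization: mean {t1.mean():+.2e}, sd {t1.std(ddof=1):.6f}")
print("Grid session means (z units):",
      np.array2string(z.scores["Grid"].mean().to_numpy(), precision=2))
# The trained task's mean rises faster than the transfer tasks' because it
# carries the task-specific step on top of the shared capacity growth.
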