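"""Parameter-recovery study: fit a simulated cohort and score the estimates.

The validation loop: simulate subjects with known parameters, fit each one
with the EM-fitted two-phase model, then report per-parameter bias and
RMSE, the transition-day error, and the fraction of subjects whose
estimated (posterior-mean) transition day lies within 1 and 2 days of the
truth.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import FitResult, fit_em, fits_to_frame
from .simulate import SimulationConfig, simulate_population, truths_frame

RECOVERED_PARAMS = ("beta_cap", "beta_ts", "alpha")


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Fitting settings forwarded to :func:`phasefit.model.fit_em`."""

    max_transition_day: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 5
    polish: bool = True


@dataclasses.dataclass
class RecoveryReport:
    """Bias, RMSE and transition-day accuracy over a simulated cohort."""

    bias: dict[str, float]
    rmse: dict[str, float]
    fraction_within: dict[int, float]
    n_subjects: int
    n_nonconverged: int
    config: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "rmse": self.rmse,
            "fraction_within": {str(k): v for k, v in self.fraction_within.items()},
            "n_subjects": self.n_subjects,
            "n_nonconverged": self.n_nonconverged,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def recover(
    fits: pd.DataFrame | Iterable[FitResult],
    truths: pd.DataFrame,
    tolerances: tuple[int, ...] = (1, 2),
) -> RecoveryReport:
    """Score estimates against truths aligned by subject id.

    bias = mean(estimate - truth); RMSE = sqrt(mean((estimate - truth)^2));
    fraction_within[k] = share of subjects whose posterior-mean transition
    day lies within k days (closed interval) of the true day.
    """
    fdf = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    fit_ids = set(fdf["subject_id"].astype(str))
    truth_ids = set(truths["subject_id"].astype(str))
    if fit_ids != truth_ids:
        only_fit = sorted(fit_ids - truth_ids)
        only_truth = sorted(truth_ids - fit_ids)
        raise ValueError(
            f"subject ids do not match: {only_fit} only in fits, {only_truth} only in truths"
        )
    merged = fdf.merge(truths, on="subject_id", suffixes=("_est", "_true"))

    bias: dict[str, float] = {}
    rmse: dict[str, float] = {}
    for p in RECOVERED_PARAMS:
        err = merged[f"{p}_est"].to_numpy(float) - merged[f"{p}_true"].to_numpy(float)
        bias[p] = float(err.mean())
        rmse[p] = float(np.sqrt(np.mean(err**2)))
    day_err = merged["transition_day_mean"].to_numpy(float) - merged["transition_day"].to_numpy(
        float
    )
    bias["transition_day"] = float(day_err.mean())
    rmse["transition_day"] = float(np.sqrt(np.mean(day_err**2)))
    fraction_within = {int(k): float(np.mean(np.abs(day_err) <= k)) for k in tolerances}

    n_nonconverged = int((~fdf["converged"].astype(bool)).sum()) if "converged" in fdf else 0
    return RecoveryReport(
        bias=bias,
        rmse=rmse,
        fraction_within=fraction_within,
        n_subjects=len(merged),
        n_nonconverged=n_nonconverged,
    )


def correlate_estimates(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and p-values) between every column pair of two aligned tables."""
    if len(set_a) != len(set_b):
        raise ValueError("tables must be aligned (equal length)")
    if len(set_a) < 3:
        raise ValueError("need at least 3 observations")
    for df, name in ((set_a, "first"), (set_b, "second")):
        for col in df.columns:
            if float(np.std(df[col].to_numpy(float))) == 0.0:
                raise ValueError(f"zero variance in column {col!r} of the {name} table")
    r = pd.DataFrame(index=set_a.columns, columns=set_b.columns, dtype=float)
    p = pd.DataFrame(index=set_a.columns, columns=set_b.columns, dtype=float)
    for ca in set_a.columns:
        for cb in set_b.columns:
            res = stats.pearsonr(set_a[ca].to_numpy(float), set_b[cb].to_numpy(float))
            r.loc[ca, cb] = res.statistic
            p.loc[ca, cb] = res.pvalue
    return r, p


def run_simulation_study(
    sim_config: SimulationConfig,
    fit_config: FitConfig | None = None,
    return_fits: bool = False,
    progress: "callable | None" = None,
):
    """Simulate a cohort, fit every subject and score the recovery.

    Deterministic under ``sim_config.seed`` (per-subject fit seeds are
    spawned from it).  Non-converged fits are included in the metrics and
    counted in the report.  With ``return_fits=True`` also returns the list
    of :class:`FitResult` and the truth table.
    """
    fit_config = fit_config or FitConfig()
    subjects = simulate_population(sim_config)
    seed_rng = np.random.default_rng(np.random.SeedSequence([sim_config.seed, 0x5EED]))
    fit_seeds = seed_rng.integers(0, 2**31 - 1, size=len(subjects))
    fits: list[FitResult] = []
    for i, subj in enumerate(subjects):
        fits.append(
            fit_em(
                subj.series,
                max_transition_day=fit_config.max_transition_day,
                tol=fit_config.tol,
                max_iter=fit_config.max_iter,
                n_restarts=fit_config.n_restarts,
                seed=int(fit_seeds[i]),
                polish=fit_config.polish,
            )
        )
        if progress is not None:
            progress(i + 1, len(subjects))
    truths = truths_frame(subjects)
    report = recover(fits_to_frame(fits), truths)
    report.config = {
        "simulation": dataclasses.asdict(sim_config),
        "fit": dataclasses.asdict(fit_config),
    }
    if return_fits:
        return report, fits, truths
    return report
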