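"""Synthetic cohorts: piecewise-linear learning curves and transfer panels.

The training-curve generator draws each subject's parameters from uniform
distributions (initial level alpha in [2, 4], task-specific rate beta_ts in
[0.8, 1.6], capacity rate beta_cap in [0.01, 0.1]) with an integer true
transition day uniform on 1..10, produces 22 unit-spaced observations and
adds zero-mean Gaussian noise.  Trajectories are continuous at the switch:
for a subject whose last phase-1 day is k the phase-2 offset is
delta_ts = beta_ts * k, so phase 2 continues where phase 1 stopped.

The transfer-panel generator emulates the dual-process latent structure of
the test battery: a single capacity factor, linear in test session, loads
on all four tasks (the trained task with loading 1.28, the rest sharing the
remainder so the loadings sum to 4), and a task-specific step is added to
the trained task from the second test session onwards.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SESSIONS, TASKS, TRANSFER_TASKS, PerformanceSeries, TransferPanel
from .model import SIGMA_FLOOR, HMMParams

TRUTH_COLUMNS = ("subject_id", "alpha", "beta_ts", "beta_cap", "transition_day")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a simulated training cohort."""

    n_subjects: int = 1000
    n_days: int = 22
    alpha_range: tuple[float, float] = (2.0, 4.0)
    beta_ts_range: tuple[float, float] = (0.8, 1.6)
    beta_cap_range: tuple[float, float] = (0.01, 0.1)
    transition_day_range: tuple[int, int] = (1, 10)
    noise_sd: float | Sequence[float] = 0.4
    max_transition_day: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_range", "beta_ts_range", "beta_cap_range", "transition_day_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (low <= high), got ({lo}, {hi})")
        if self.transition_day_range[1] >= self.n_days:
            raise ValueError("transition days must fall strictly before the last day")
        if np.any(np.asarray(self.noise_sd, dtype=float) < 0):
            raise ValueError("noise_sd must be >= 0")

    def noise_vector(self) -> np.ndarray:
        """Per-day noise sd, broadcast to length n_days."""
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(self.n_days, float(sd))
        if len(sd) != self.n_days:
            raise ValueError("per-day noise_sd must have length n_days")
        return sd


@dataclasses.dataclass(frozen=True)
class SimulatedSubject:
    """A generated series paired with its known true parameters."""

    series: PerformanceSeries
    truth: HMMParams
    transition_day: int


def piecewise_mean(
    alpha: float, beta_ts: float, beta_cap: float, transition_day: int, times: np.ndarray
) -> np.ndarray:
    """Noise-free trajectory, continuous at the switch (delta = beta_ts * k)."""
    times = np.asarray(times, dtype=float)
    phase1 = (beta_cap + beta_ts) * times + alpha
    phase2 = beta_cap * times + beta_ts * transition_day + alpha
    return np.where(times <= transition_day, phase1, phase2)


def simulate_subject(
    config: SimulationConfig, rng: np.random.Generator, subject_id: str = "sim"
) -> SimulatedSubject:
    """Draw one subject's true parameters and generate its noisy series."""
    alpha = rng.uniform(*config.alpha_range)
    beta_ts = rng.uniform(*config.beta_ts_range)
    beta_cap = rng.uniform(*config.beta_cap_range)
    k_lo, k_hi = config.transition_day_range
    k = int(rng.integers(k_lo, k_hi + 1))
    times = np.arange(1, config.n_days + 1, dtype=float)
    noise = config.noise_vector()
    y = piecewise_mean(alpha, beta_ts, beta_cap, k, times) + rng.normal(0.0, 1.0, len(times)) * noise
    y = np.maximum(y, 1e-6)  # levels are positive by construction of the score
    truth = HMMParams(
        beta_cap=beta_cap,
        beta_ts=beta_ts,
        alpha=alpha,
        tau=1.0 / k,
        sigma=max(float(np.mean(noise)), SIGMA_FLOOR),
    )
    return SimulatedSubject(PerformanceSeries(subject_id, times, y), truth, k)


def simulate_population(config: SimulationConfig) -> list[SimulatedSubject]:
    """Independent draws of ``config.n_subjects`` subjects, seeded by the config."""
    rng = np.random.default_rng(config.seed)
    width = max(len(str(max(config.n_subjects, 1))), 3)
    return [
        simulate_subject(config, rng, subject_id=f"s{i:0{width}d}")
        for i in range(config.n_subjects)
    ]


def truths_frame(subjects: Sequence[SimulatedSubject]) -> pd.DataFrame:
    """True parameter table in the truth-CSV dialect."""
    rows = [
        {
            "subject_id": s.series.subject_id,
            "alpha": s.truth.alpha,
            "beta_ts": s.truth.beta_ts,
            "beta_cap": s.truth.beta_cap,
            "transition_day": s.transition_day,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


@dataclasses.dataclass(frozen=True)
class PanelConfig:
    """Generative settings for a synthetic transfer-test panel.

    ``cap_intercept``, ``cap_slope`` and ``ts_step`` are (mean, sd) pairs of
    normal distributions for, respectively, each subject's baseline capacity,
    per-session capacity growth, and the trained-task-specific step applied
    from the second session onwards.  The four factor loadings must sum to 4
    and the three transfer-task intercepts to 0.
    """

    n_subjects: int = 200
    loading_grid: float = 1.28
    loadings_transfer: tuple[float, float, float] | None = None
    intercepts_transfer: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cap_intercept: tuple[float, float] = (0.0, 1.0)
    cap_slope: tuple[float, float] = (0.5, 0.2)
    ts_step: tuple[float, float] = (1.0, 0.3)
    residual_sd: float = 0.3
    seed: int = 0

    def resolved_loadings(self) -> dict[str, float]:
        if self.loadings_transfer is None:
            rest = (4.0 - self.loading_grid) / 3.0
            transfer = (rest, rest, rest)
        else:
            transfer = self.loadings_transfer
        loadings = {"Grid": self.loading_grid}
        loadings.update(dict(zip(TRANSFER_TASKS, transfer)))
        if abs(sum(loadings.values()) - 4.0) > 1e-9:
            raise ValueError("the four factor loadings must sum to 4")
        if abs(sum(self.intercepts_transfer)) > 1e-9:
            raise ValueError("the three transfer-task intercepts must sum to 0")
        return loadings


def simulate_transfer_panel(
    config: PanelConfig, rng: np.random.Generator | None = None
) -> tuple[TransferPanel, pd.DataFrame]:
    """Generate a panel plus its per-subject latent truth table.

    score(task, session) = loading_task * Cap_i(session) + intercept_task
                           + TS_i * [task == Grid] * [session >= 2] + noise
    with Cap_i linear in session.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    loadings = config.resolved_loadings()
    intercepts = {"Grid": 0.0}
    intercepts.update(dict(zip(TRANSFER_TASKS, config.intercepts_transfer)))
    n = config.n_subjects
    a = rng.normal(*config.cap_intercept, n)
    b = rng.normal(*config.cap_slope, n)
    ts = rng.normal(*config.ts_step, n)
    ids = [f"p{i:03d}" for i in range(n)]
    cols = pd.MultiIndex.from_tuples(
        [(t, s) for t in TASKS for s in SESSIONS], names=["task", "session"]
    )
    scores = np.empty((n, len(cols)))
    for j, (task, s) in enumerate(cols):
        cap = a + b * (s - 1)
        mean = loadings[task] * cap + intercepts[task]
        if task == "Grid" and s >= 2:
            mean = mean + ts
        scores[:, j] = mean + rng.normal(0.0, config.residual_sd, n)
    truth = pd.DataFrame(
        {"subject_id": ids, "cap_intercept": a, "cap_slope": b, "ts_step": ts}
    )
    panel = TransferPanel(pd.DataFrame(scores, index=ids, columns=cols))
    return panel, truth


def inject_missingness(
    panel: TransferPanel,
    rate: float,
    rng: np.random.Generator,
    tasks: Sequence[str] = TRANSFER_TASKS,
) -> TransferPanel:
    """Blank each cell of the given tasks independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    scores = panel.scores.copy()
    for col in scores.columns:
        if col[0] in tasks:
            mask = rng.random(len(scores)) < rate
            scores.loc[mask, col] = np.nan
    return TransferPanel(scores)
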