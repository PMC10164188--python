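"""Two-phase piecewise-linear learning-curve model fitted as a left-to-right HMM.

A subject's daily training performance is modelled with two consecutive
phases.  In phase 1 a fast task-specific process and a slow capacity process
improve together; in phase 2 the task-specific process has saturated and
only the capacity process continues:

    phase 1:  y_t = (beta_cap + beta_ts) * t + alpha + w_t
    phase 2:  y_t = beta_cap * t + delta_ts + alpha + w_t

with white noise w_t ~ N(0, sigma^2) and delta_ts = beta_ts / tau the
expected accumulated task-specific gain at the switch.  The hidden phase
follows a two-state left-to-right Markov chain: every subject starts in
phase 1, moves to phase 2 with per-day probability tau, and never returns.
The last day generated by phase 1 (the "transition day" k) therefore has a
geometric prior (1 - tau)^(k - 1) * tau, truncated to an allowed support
1..min(N - 1, max_transition_day).

Fitting is per-subject maximum likelihood by expectation-maximization: the
E-step computes the posterior over the transition day (and hence per-day
phase probabilities), the M-step re-estimates (beta_cap, beta_ts, alpha,
tau, sigma) against the expected complete-data log likelihood.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import PerformanceSeries

TAU_MIN = 1e-6
SIGMA_FLOOR = 1e-4
DEFAULT_MAX_TRANSITION_DAY = 10

_LOG_2PI = float(np.log(2.0 * np.pi))


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    if not np.isfinite(m):
        return m
    return m + math.log(float(np.exp(x - m).sum()))


@dataclasses.dataclass(frozen=True)
class HMMParams:
    """The five model parameters.

    beta_cap : capacity improvement rate (levels/day)
    beta_ts  : task-specific improvement rate during phase 1 (levels/day)
    alpha    : initial performance level (levels)
    tau      : per-day phase-1 -> phase-2 transition probability, in (0, 1]
    sigma    : emission noise standard deviation (levels), > 0
    """

    beta_cap: float
    beta_ts: float
    alpha: float
    tau: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("beta_cap", "beta_ts", "alpha", "tau", "sigma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def delta_ts(self) -> float:
        """Total task-specific gain at the switch, beta_ts / tau."""
        return self.beta_ts / self.tau


def delta_ts(params: HMMParams) -> float:
    """Accumulated task-specific improvement beta_ts / tau."""
    if params.tau == 0:
        raise ValueError("tau must be > 0")
    return params.beta_ts / params.tau


def predict_mean(params: HMMParams, t, phase: int):
    """Mean performance level on day ``t`` under the given phase."""
    t = np.asarray(t, dtype=float)
    if phase == 1:
        out = (params.beta_cap + params.beta_ts) * t + params.alpha
    elif phase == 2:
        out = params.beta_cap * t + params.delta_ts + params.alpha
    else:
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    return out if out.ndim else float(out)


def emission_logpdf(params: HMMParams, y, t, phase: int):
    """Gaussian log density of observing level ``y`` on day ``t`` in ``phase``."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("observed level must be finite")
    m = predict_mean(params, t, phase)
    out = -0.5 * _LOG_2PI - np.log(params.sigma) - (y - m) ** 2 / (2.0 * params.sigma**2)
    return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class PhasePosterior:
    """Posterior over the transition day and per-day phase probabilities.

    ``support`` holds the candidate last-phase-1 days; ``trans_pmf`` the
    normalized posterior mass over them.  ``phase1_prob[i]`` is the
    posterior probability that observation i was generated in phase 1
    (complementary to ``phase2_prob[i]``).  ``log_evidence`` is the
    observed-data log likelihood at the parameters used to build it.
    """

    support: np.ndarray
    trans_pmf: np.ndarray
    phase1_prob: np.ndarray
    phase2_prob: np.ndarray
    log_evidence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=int))
        object.__setattr__(self, "trans_pmf", np.asarray(self.trans_pmf, dtype=float))
        object.__setattr__(self, "phase1_prob", np.asarray(self.phase1_prob, dtype=float))
        object.__setattr__(self, "phase2_prob", np.asarray(self.phase2_prob, dtype=float))
        if abs(self.trans_pmf.sum() - 1.0) > 1e-10:
            raise ValueError("transition pmf must sum to 1")
        if np.any(np.abs(self.phase1_prob + self.phase2_prob - 1.0) > 1e-10):
            raise ValueError("phase posteriors must be complementary at every day")


def estimate_transition_day(posterior: PhasePosterior) -> tuple[float, int]:
    """Posterior-mean (continuous) and MAP (earliest tie) transition day."""
    mean_day = float(posterior.support @ posterior.trans_pmf)
    map_day = int(posterior.support[int(np.argmax(posterior.trans_pmf))])
    return mean_day, map_day


def _support(series: PerformanceSeries, max_transition_day: int) -> np.ndarray:
    n = len(series)
    k_max = min(n - 1, int(max_transition_day))
    if k_max < 1:
        raise ValueError("max_transition_day must allow at least one candidate day")
    return np.arange(1, k_max + 1)


def _phase_loglikes(params: HMMParams, times: np.ndarray, levels: np.ndarray):
    m1 = (params.beta_cap + params.beta_ts) * times + params.alpha
    m2 = params.beta_cap * times + params.delta_ts + params.alpha
    c = -0.5 * _LOG_2PI - np.log(params.sigma)
    inv = 0.5 / params.sigma**2
    return c - inv * (levels - m1) ** 2, c - inv * (levels - m2) ** 2


def _log_geometric_prior(support: np.ndarray, tau: float) -> np.ndarray:
    k = support.astype(float)
    if tau >= 1.0:
        return np.where(k == 1.0, 0.0, -np.inf)
    return (k - 1.0) * np.log1p(-tau) + np.log(tau)


def _log_joint(
    params: HMMParams, times: np.ndarray, levels: np.ndarray, support: np.ndarray
) -> np.ndarray:
    """log p(transition day = k, y) for every candidate k in the support."""
    l1, l2 = _phase_loglikes(params, times, levels)
    c1 = np.cumsum(l1)
    c2 = np.cumsum(l2)
    total2 = c2[-1]
    # number of observations with time <= k: phase-1 block size per candidate
    head_n = np.searchsorted(times, support, side="right")
    head = np.where(head_n > 0, c1[np.maximum(head_n - 1, 0)], 0.0)
    tail = total2 - np.where(head_n > 0, c2[np.maximum(head_n - 1, 0)], 0.0)
    return _log_geometric_prior(support, params.tau) + head + tail


def log_likelihood(
    params: HMMParams,
    series: PerformanceSeries,
    max_transition_day: int = DEFAULT_MAX_TRANSITION_DAY,
) -> float:
    """Observed-data log likelihood, marginalizing over the transition day."""
    support = _support(series, max_transition_day)
    return _logsumexp(_log_joint(params, series.times, series.levels, support))


def transition_pmf(
    params: HMMParams,
    series: PerformanceSeries,
    max_transition_day: int = DEFAULT_MAX_TRANSITION_DAY,
) -> PhasePosterior:
    """Posterior over the transition day given one subject's series.

    Candidate transition day k (the last day generated by phase 1) carries
    weight (1-tau)^(k-1) * tau times the phase-1 likelihood of observations
    up to and including day k times the phase-2 likelihood after it; weights
    are computed in log space and normalized over the allowed support.  The
    per-day phase probabilities are the cumulative sums of the pmf: a day t
    is in phase 1 iff the transition happens on day t or later.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 observations")
    support = _support(series, max_transition_day)
    times, levels = series.times, series.levels
    logw = _log_joint(params, times, levels, support)
    log_ev = _logsumexp(logw)
    if not np.isfinite(log_ev):
        raise FloatingPointError("all transition-day weights vanished")
    pmf = np.exp(logw - log_ev)
    pmf = pmf / pmf.sum()
    cum = np.cumsum(pmf)
    # phase 2 on day t  <=>  transition day k < t
    below = np.searchsorted(support, times, side="left")
    p2 = np.where(below > 0, cum[np.maximum(below - 1, 0)], 0.0)
    p2 = np.clip(p2, 0.0, 1.0)
    return PhasePosterior(support, pmf, 1.0 - p2, p2, log_ev)


def e_step(
    params: HMMParams,
    series: PerformanceSeries,
    max_transition_day: int = DEFAULT_MAX_TRANSITION_DAY,
) -> PhasePosterior:
    """E-step: the full transition-day posterior at the current parameters."""
    return transition_pmf(params, series, max_transition_day)


def _expected_loglik(
    beta_cap: float,
    beta_ts: float,
    alpha: float,
    tau: float,
    sigma: float,
    times: np.ndarray,
    levels: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    mean_k: float,
) -> float:
    """Expected complete-data log likelihood under fixed phase weights."""
    if tau >= 1.0:
        prior = 0.0 if mean_k <= 1.0 + 1e-12 else -np.inf
    elif tau < TAU_MIN:
        return -np.inf
    else:
        prior = (mean_k - 1.0) * np.log1p(-tau) + np.log(tau)
    if not np.isfinite(prior):
        return -np.inf
    m1 = (beta_cap + beta_ts) * times + alpha
    m2 = beta_cap * times + beta_ts / tau + alpha
    c = -0.5 * _LOG_2PI - np.log(sigma)
    inv = 0.5 / sigma**2
    em = np.sum(w1 * (c - inv * (levels - m1) ** 2) + w2 * (c - inv * (levels - m2) ** 2))
    return float(em + prior)


_TAU_GRID = np.geomspace(1e-4, 1.0, 41)


def _optimize_tau(
    beta_ts: float,
    sigma: float,
    tau_current: float,
    d: np.ndarray,
    w2: np.ndarray,
    mean_k: float,
) -> float:
    """1-D maximization of the expected loglik over tau (guarded).

    ``d = levels - beta_cap * times - alpha`` so the phase-2 residual at a
    given tau is ``d - beta_ts / tau``; its weighted sum of squares reduces
    to three precomputed moments, making each evaluation O(1).  A coarse
    grid brackets the optimum, Brent refines it, and the current tau is
    always a fallback candidate so the step never decreases the objective.
    """
    s0 = float(w2.sum())
    s1 = float(w2 @ d)
    s2 = float(w2 @ (d * d))
    inv = 0.5 / (sigma * sigma)
    ek1 = mean_k - 1.0

    def g(tau: float) -> float:
        if not TAU_MIN <= tau <= 1.0:
            return -np.inf
        if tau >= 1.0:
            prior = 0.0 if ek1 <= 1e-12 else -np.inf
        else:
            prior = ek1 * math.log1p(-tau) + math.log(tau)
        if not np.isfinite(prior):
            return -np.inf
        c = beta_ts / tau
        return prior - inv * (s2 - 2.0 * c * s1 + c * c * s0)

    grid = np.append(_TAU_GRID, [tau_current, min(1.0, max(TAU_MIN, 1.0 / max(mean_k, 1.0)))])
    grid.sort()
    # vectorized grid pass; -inf where the prior degenerates
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = np.where(
            grid >= 1.0,
            0.0 if ek1 <= 1e-12 else -np.inf,
            ek1 * np.log1p(-np.minimum(grid, 1.0 - 1e-300)) + np.log(grid),
        )
    cg = beta_ts / grid
    vals = gp - inv * (s2 - 2.0 * cg * s1 + cg * cg * s0)
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    cand = [tau_current, float(grid[best])]
    if hi > lo:
        cand.append(_golden_max(g, lo, hi))

    def g_direct(tau: float) -> float:
        # final guard in direct residual form: the moment form cancels
        # catastrophically near exact fits, where 1/sigma^2 amplifies the
        # rounding error enough to break the ascent guarantee
        if not TAU_MIN <= tau <= 1.0:
            return -np.inf
        if tau >= 1.0:
            prior = 0.0 if ek1 <= 1e-12 else -np.inf
        else:
            prior = ek1 * math.log1p(-tau) + math.log(tau)
        if not np.isfinite(prior):
            return -np.inf
        r = d - beta_ts / tau
        return prior - inv * float(w2 @ (r * r))

    return max(cand, key=g_direct)


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(g, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Golden-section maximization on [lo, hi]; value-comparison based."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    gc, gd = g(c), g(d)
    while b - a > tol:
        if gc >= gd:
            b, d, gd = d, c, gc
            c = b - _INVPHI * (b - a)
            gc = g(c)
        else:
            a, c, gc = c, d, gd
            d = a + _INVPHI * (b - a)
            gd = g(d)
    return 0.5 * (a + b)


def m_step(
    series: PerformanceSeries,
    posterior: PhasePosterior,
    current: HMMParams,
    n_cycles: int = 2,
) -> HMMParams:
    """M-step: re-estimate all five parameters against the expected loglik.

    Coordinate ascent — posterior-weighted least squares for the linear
    coefficients at fixed tau, a guarded 1-D search for tau, then the
    closed-form sigma (posterior-weighted root mean squared residual).
    Every sub-step is exact or guarded, so the objective never decreases;
    if floating point says otherwise the incoming parameters are returned.
    """
    w1 = posterior.phase1_prob
    w2 = posterior.phase2_prob
    mean_k = float(posterior.support @ posterior.trans_pmf)
    out = _m_step_core(series.times, series.levels, w1, w2, mean_k, current, n_cycles)
    return HMMParams(*out)


def _slope_bound(levels: np.ndarray) -> float:
    """Cap on improvement-rate magnitudes: a per-day rate larger than the
    series' total range is never data-supported, only ridge-degenerate."""
    return max(float(np.ptp(levels)), 1.0)


def _m_step_core(
    times: np.ndarray,
    levels: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    mean_k: float,
    current: HMMParams,
    n_cycles: int = 2,
    slope_bound: float | None = None,
) -> tuple[float, float, float, float, float]:
    n = len(levels)
    if slope_bound is None:
        slope_bound = _slope_bound(levels)
    beta_cap, beta_ts, alpha = current.beta_cap, current.beta_ts, current.alpha
    tau, sigma = current.tau, current.sigma
    q_in = _expected_loglik(
        beta_cap, beta_ts, alpha, tau, sigma, times, levels, w1, w2, mean_k
    )

    # weighted moments shared by the normal equations of every cycle
    t2 = times * times
    ty = times * levels
    s1w, s1t, s1tt = float(w1.sum()), float(w1 @ times), float(w1 @ t2)
    s1y, s1ty = float(w1 @ levels), float(w1 @ ty)
    s2w, s2t, s2tt = float(w2.sum()), float(w2 @ times), float(w2 @ t2)
    s2y, s2ty = float(w2 @ levels), float(w2 @ ty)
    for _ in range(n_cycles):
        # linear coefficients: posterior-weighted least squares at fixed tau
        u = 1.0 / tau
        G = np.array(
            [
                [s1tt + s2tt, s1tt + u * s2t, s1t + s2t],
                [s1tt + u * s2t, s1tt + u * u * s2w, s1t + u * s2w],
                [s1t + s2t, s1t + u * s2w, s1w + s2w],
            ]
        )
        h = np.array([s1ty + s2ty, s1ty + u * s2y, s1y + s2y])
        try:
            coef = np.linalg.solve(G, h)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(G, h, rcond=None)
        if not np.all(np.isfinite(coef)):
            coef, *_ = np.linalg.lstsq(G, h, rcond=None)
        beta_cap, beta_ts, alpha = (float(c) for c in coef)
        if abs(beta_ts) > slope_bound:
            # near-collinear tau -> 1 ridge: cap the task-specific rate at a
            # physically meaningful bound and re-solve the other coefficients
            beta_ts = math.copysign(slope_bound, beta_ts)
            g2 = np.array([[s1tt + s2tt, s1t + s2t], [s1t + s2t, s1w + s2w]])
            h2 = np.array(
                [
                    s1ty + s2ty - beta_ts * (s1tt + u * s2t),
                    s1y + s2y - beta_ts * (s1t + u * s2w),
                ]
            )
            try:
                beta_cap, alpha = (float(c) for c in np.linalg.solve(g2, h2))
            except np.linalg.LinAlgError:
                beta_cap, alpha = (
                    float(c) for c in np.linalg.lstsq(g2, h2, rcond=None)[0]
                )
        tau = _optimize_tau(
            beta_ts, sigma, tau, levels - beta_cap * times - alpha, w2, mean_k
        )
        r1 = levels - (beta_cap + beta_ts) * times - alpha
        r2 = levels - beta_cap * times - beta_ts / tau - alpha
        sigma = max(float(np.sqrt((w1 @ (r1 * r1) + w2 @ (r2 * r2)) / n)), SIGMA_FLOOR)

    q_out = _expected_loglik(
        beta_cap, beta_ts, alpha, tau, sigma, times, levels, w1, w2, mean_k
    )
    if not np.isfinite(q_out) or q_out < q_in:
        return (
            current.beta_cap,
            current.beta_ts,
            current.alpha,
            current.tau,
            current.sigma,
        )
    return beta_cap, beta_ts, alpha, tau, sigma


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Per-subject fit: parameters, posterior and fitting diagnostics."""

    subject_id: str
    params: HMMParams
    posterior: PhasePosterior
    transition_day: float
    transition_day_map: int
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(t) >= 2 and np.ptp(t) > 0:
        slope, intercept = np.polyfit(t, y, 1)
        return float(slope), float(intercept)
    return 0.0, float(y[0]) if len(y) else 0.0


def _initial_candidates(
    series: PerformanceSeries,
    support: np.ndarray,
    max_transition_day: int,
    exhaustive: bool = False,
) -> list[HMMParams]:
    """Starting points: a slope-split heuristic and a pure-line candidate.

    The heuristic reads the capacity rate off the last half of the series,
    the task-specific rate off the first five observations, and the noise
    off a single-line fit.  The second candidate is the pure line (no
    task-specific phase, immediate transition).  By default no further
    starts are generated: for weak-signal subjects the marginal likelihood
    is nearly flat in the transition day, and starting EM from exhaustive
    segmentations would chase noise kinks.  With ``exhaustive=True`` (the
    global maximum-likelihood search) one hard-segmentation least-squares
    start per candidate transition day is appended, ranked by initial
    likelihood.
    """
    t, y = series.times, series.levels
    n = len(t)
    half = max(n // 2, 2)
    s_late, _ = _line_fit(t[-half:], y[-half:])
    s_early, _ = _line_fit(t[: min(5, n)], y[: min(5, n)])
    s_all, c_all = _line_fit(t, y)
    sigma_all = max(float(np.std(y - s_all * t - c_all)), SIGMA_FLOOR)
    bound = _slope_bound(y)
    cands = [
        HMMParams(s_late, max(s_early - s_late, 0.0), float(y[0]), 0.5, sigma_all),
        HMMParams(s_all, 0.0, float(c_all), 1.0, sigma_all),
    ]
    cands.sort(key=lambda p: log_likelihood(p, series, max_transition_day), reverse=True)
    if not exhaustive:
        return cands
    seg: list[tuple[float, HMMParams]] = []
    for k in support:
        m = int(np.searchsorted(t, k, side="right"))
        if m < 1 or m >= n:
            continue
        s2, c2 = _line_fit(t[m:], y[m:])
        if m >= 2:
            s1, c1 = _line_fit(t[:m], y[:m])
        else:
            s1 = (y[1] - y[0]) / (t[1] - t[0])
            c1 = y[0] - s1 * t[0]
        beta_ts = float(np.clip(s1 - s2, -bound, bound))
        delta = c2 - c1
        if beta_ts > 1e-9 and delta > 1e-9:
            tau0 = float(np.clip(beta_ts / delta, TAU_MIN, 1.0))
        else:
            tau0 = float(np.clip(1.0 / k, TAU_MIN, 1.0))
        resid = np.concatenate([y[:m] - s1 * t[:m] - c1, y[m:] - s2 * t[m:] - c2])
        sigma0 = max(float(np.sqrt(np.mean(resid**2))), SIGMA_FLOOR)
        try:
            p = HMMParams(s2, beta_ts, float(c1), tau0, sigma0)
        except ValueError:
            continue
        seg.append((log_likelihood(p, series, max_transition_day), p))
    seg.sort(key=lambda sp: sp[0], reverse=True)
    return cands + [p for _, p in seg]


def _jitter(params: HMMParams, rng: np.random.Generator) -> HMMParams:
    """Mild perturbation of a start; guards against degenerate initials
    without turning the restarts into a global search."""
    beta_cap = params.beta_cap * float(np.exp(rng.normal(0.0, 0.05)))
    beta_ts = params.beta_ts * float(np.exp(rng.normal(0.0, 0.05))) + float(
        rng.normal(0.0, 0.01)
    )
    alpha = params.alpha + float(rng.normal(0.0, 0.05 * max(params.sigma, 0.1)))
    tau = float(
        np.clip(
            expit(logit(np.clip(params.tau, 1e-6, 1.0 - 1e-6)) + rng.normal(0.0, 0.1)),
            TAU_MIN,
            1.0,
        )
    )
    sigma = max(params.sigma * float(np.exp(rng.normal(0.0, 0.05))), SIGMA_FLOOR)
    return HMMParams(beta_cap, beta_ts, alpha, tau, sigma)


def _polish(
    params: HMMParams, series: PerformanceSeries, max_transition_day: int
) -> tuple[HMMParams, float]:
    """Joint Nelder-Mead refinement of all five parameters on the loglik."""

    bound = _slope_bound(series.levels)

    def clipped(x: np.ndarray) -> HMMParams:
        return HMMParams(
            float(np.clip(x[0], -bound, bound)),
            float(np.clip(x[1], -bound, bound)),
            float(x[2]),
            float(np.clip(x[4], TAU_MIN, 1.0)),
            float(max(x[3], SIGMA_FLOOR)),
        )

    def nll(x: np.ndarray) -> float:
        try:
            return -log_likelihood(clipped(x), series, max_transition_day)
        except (ValueError, FloatingPointError):
            return np.inf

    x0 = np.array([params.beta_cap, params.beta_ts, params.alpha, params.sigma, params.tau])
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"maxiter": 500, "xatol": 1e-10, "fatol": 1e-12},
    )
    out = clipped(res.x)
    return out, log_likelihood(out, series, max_transition_day)


def fit_em(
    series: PerformanceSeries,
    max_transition_day: int = DEFAULT_MAX_TRANSITION_DAY,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
    polish: bool = True,
    selection: str = "penalized",
) -> FitResult:
    """Fit the two-phase model to one subject by EM, best of several starts.

    Starts are a slope-split heuristic and a pure-line candidate plus
    jittered copies; each runs EM until the log likelihood moves by less
    than ``tol`` or ``max_iter`` is reached, followed by an optional joint
    Nelder-Mead polish that is kept only when it improves the likelihood.
    The search is deliberately local: for weak-signal subjects the marginal
    likelihood is nearly flat in the transition day and an exhaustive
    search would reward spurious noise kinks.

    ``selection`` controls the final model choice.  The default
    ``"penalized"`` compares the best interior fit against the degenerate
    single-line solution (immediate transition, no task-specific phase) by
    AIC, falling back to the line when the two-phase structure is not
    supported by the data; ``"ml"`` always returns the highest-likelihood
    interior fit.
    """
    if len(series) < 4:
        raise ValueError(f"subject {series.subject_id!r}: need at least 4 observations")
    if selection not in ("penalized", "ml"):
        raise ValueError(f"selection must be 'penalized' or 'ml', got {selection!r}")
    support = _support(series, max_transition_day)
    rng = np.random.default_rng(seed)
    cands = _initial_candidates(
        series, support, max_transition_day, exhaustive=(selection == "ml")
    )
    starts = cands[:n_restarts]
    i = 0
    while len(starts) < n_restarts:
        starts.append(_jitter(cands[i % len(cands)], rng))
        i += 1

    times, levels = series.times, series.levels
    ksupp = support.astype(float)
    # candidate index strictly below each observation day
    below = np.searchsorted(support, times, side="left")

    def estep_arrays(p: HMMParams):
        logw = _log_joint(p, times, levels, support)
        ll = _logsumexp(logw)
        pmf = np.exp(logw - ll)
        pmf /= pmf.sum()
        cum = np.cumsum(pmf)
        p2 = np.where(below > 0, cum[np.maximum(below - 1, 0)], 0.0)
        p2 = np.clip(p2, 0.0, 1.0)
        return ll, pmf, 1.0 - p2, p2

    def extrapolate(old: HMMParams, new: HMMParams, factor: float) -> HMMParams | None:
        """Step-lengthening candidate along the last EM move, kept in bounds."""
        try:
            return HMMParams(
                new.beta_cap + factor * (new.beta_cap - old.beta_cap),
                new.beta_ts + factor * (new.beta_ts - old.beta_ts),
                new.alpha + factor * (new.alpha - old.alpha),
                float(np.clip(new.tau + factor * (new.tau - old.tau), TAU_MIN, 1.0)),
                max(new.sigma + factor * (new.sigma - old.sigma), SIGMA_FLOOR),
            )
        except ValueError:
            return None

    best: tuple[float, HMMParams, list[float], bool] | None = None
    for start in starts:
        params = start
        trace: list[float] = []
        converged = False
        ll, pmf, w1, w2 = estep_arrays(params)
        trace.append(ll)
        for _ in range(max_iter):
            mean_k = float(ksupp @ pmf)
            old = params
            params = HMMParams(*_m_step_core(times, levels, w1, w2, mean_k, params))
            ll, pmf, w1, w2 = estep_arrays(params)
            # guarded step-lengthening: EM moves can be tiny along ridges;
            # accept a doubled step only when the log likelihood improves
            factor = 1.0
            while factor <= 16.0:
                cand = extrapolate(old, params, factor)
                if cand is None:
                    break
                ll_c, pmf_c, w1_c, w2_c = estep_arrays(cand)
                if ll_c > ll:
                    params, ll, pmf, w1, w2 = cand, ll_c, pmf_c, w1_c, w2_c
                    factor *= 2.0
                else:
                    break
            if ll < trace[-1]:
                # EM cannot decrease the likelihood; a measured decrease
                # means floating point is exhausted -> keep the previous
                # iterate and stop
                params = old
                converged = True
                break
            trace.append(ll)
            if abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, trace, converged)

    assert best is not None
    loglik, params, trace, converged = best
    if polish:
        polished, ll_pol = _polish(params, series, max_transition_day)
        if ll_pol > loglik:
            params = polished
            loglik = ll_pol
            trace = trace + [ll_pol]
    if selection == "penalized":
        # Compare against the boundary-degenerate single-line solution
        # (no task-specific phase, switch on day 1: beta_ts = 0, tau = 1),
        # which has two fewer free parameters.  An interior fit must beat it
        # by more than the AIC margin for those parameters, otherwise its
        # likelihood advantage is indistinguishable from noise fitting and
        # the transition day would be set by the prior alone.
        slope, intercept = _line_fit(times, levels)
        resid = levels - slope * times - intercept
        sigma_line = max(float(np.sqrt(np.mean(resid * resid))), SIGMA_FLOOR)
        try:
            line = HMMParams(slope, 0.0, intercept, 1.0, sigma_line)
            ll_line = log_likelihood(line, series, max_transition_day)
        except (ValueError, FloatingPointError):
            ll_line = -np.inf
        if loglik - ll_line < 2.0:
            params, loglik, trace, converged = line, ll_line, [ll_line], True
    post = transition_pmf(params, series, max_transition_day)
    mean_day, map_day = estimate_transition_day(post)
    return FitResult(
        subject_id=series.subject_id,
        params=params,
        posterior=post,
        transition_day=mean_day,
        transition_day_map=map_day,
        loglik=loglik,
        n_iter=len(trace) - 1,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


FIT_COLUMNS = (
    "subject_id",
    "beta_cap",
    "beta_ts",
    "alpha",
    "tau",
    "sigma",
    "delta_ts",
    "transition_day_mean",
    "transition_day_map",
    "loglik",
    "n_iter",
    "converged",
)


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Tabulate per-subject fits in the canonical output dialect."""
    rows = [
        {
            "subject_id": f.subject_id,
            "beta_cap": f.params.beta_cap,
            "beta_ts": f.params.beta_ts,
            "alpha": f.params.alpha,
            "tau": f.params.tau,
            "sigma": f.params.sigma,
            "delta_ts": f.params.delta_ts,
            "transition_day_mean": f.transition_day,
            "transition_day_map": f.transition_day_map,
            "loglik": f.loglik,
            "n_iter": f.n_iter,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows, columns=list(FIT_COLUMNS))


def flag_outliers(
    fits: Iterable[FitResult] | pd.DataFrame, multiplier: float = 10.0
) -> list[str]:
    """Subjects whose beta_cap exceeds ``multiplier`` x the cohort sd.

    The sd (ddof=1) is computed in a single pass over all subjects,
    including any candidate outlier; a degenerate sd of zero flags nobody.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    if len(df) < 2:
        raise ValueError("need at least 2 fits")
    values = df["beta_cap"].to_numpy(dtype=float)
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return []
    mask = values > multiplier * sd
    return [str(s) for s in df.loc[mask, "subject_id"]]
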