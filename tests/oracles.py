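"""Independent reference implementations used to check the package.

Everything here is deliberately naive — exhaustive enumeration, direct
formulas, dense distance computation — and shares no code with the
implementation it verifies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from phasefit import HMMParams, PerformanceSeries, log_likelihood


def gaussian_logpdf(y: float, mean: float, sd: float) -> float:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - (y - mean) ** 2 / (2 * sd**2)


def brute_force_pmf(params: HMMParams, series: PerformanceSeries, max_td: int) -> np.ndarray:
    """Transition-day pmf by direct weight multiplication over all placements."""
    t, y = series.times, series.levels
    weights = []
    k_max = min(len(t) - 1, max_td)
    for k in range(1, k_max + 1):
        prior = (1 - params.tau) ** (k - 1) * params.tau
        lik = 1.0
        for ti, yi in zip(t, y):
            if ti <= k:
                mean = (params.beta_cap + params.beta_ts) * ti + params.alpha
            else:
                mean = params.beta_cap * ti + params.beta_ts / params.tau + params.alpha
            lik *= np.exp(gaussian_logpdf(yi, mean, params.sigma))
        weights.append(prior * lik)
    weights = np.asarray(weights)
    return weights / weights.sum()


def brute_force_fit(
    series: PerformanceSeries, max_td: int
) -> tuple[float, HMMParams, int]:
    """Exhaustive transition-day enumeration with per-segment ML fitting.

    For each candidate last-phase-1 day the three linear coefficients are
    profiled out by least squares at fixed tau, sigma by its closed form,
    and tau by a dense grid plus local refinement.  Rates are kept inside
    the same bound as the fitted model (the series' total range): without
    it the likelihood has a degenerate beta_ts -> inf, tau -> 1 ridge whose
    supremum is not attained by any finite parameter vector.

    Returns the best candidate's marginal log likelihood (as computed by
    the package's likelihood on the oracle's parameters), the parameters,
    and the segmentation day.
    """
    t, y = series.times, series.levels
    n = len(t)
    k_max = min(n - 1, max_td)
    bound = max(float(np.ptp(y)), 1.0)

    def fit_at(k: int, m: int, tau: float):
        A = np.zeros((n, 3))
        A[:m, 0] = t[:m]
        A[:m, 1] = t[:m]
        A[:m, 2] = 1.0
        A[m:, 0] = t[m:]
        A[m:, 1] = 1.0 / tau
        A[m:, 2] = 1.0
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if abs(coef[1]) > bound:
            bt = float(np.sign(coef[1]) * bound)
            A2 = np.column_stack([t, np.ones(n)])
            y2 = y.copy()
            y2[:m] -= bt * t[:m]
            y2[m:] -= bt / tau
            c2, *_ = np.linalg.lstsq(A2, y2, rcond=None)
            coef = np.array([c2[0], bt, c2[1]])
        pred = np.where(
            np.arange(n) < m,
            (coef[0] + coef[1]) * t + coef[2],
            coef[0] * t + coef[1] / tau + coef[2],
        )
        resid = y - pred
        sigma = max(float(np.sqrt(np.mean(resid**2))), 1e-4)
        ll = (
            (k - 1) * np.log1p(-tau)
            + np.log(tau)
            + sum(gaussian_logpdf(r + 0.0, 0.0, sigma) for r in resid)
        )
        return float(ll), coef, sigma

    best = None
    for k in range(1, k_max + 1):
        m = int(np.searchsorted(t, k, side="right"))

        def nll(tau: float) -> float:
            if not 1e-6 <= tau <= 1 - 1e-12:
                return np.inf
            return -fit_at(k, m, tau)[0]

        taus = np.geomspace(1e-4, 1 - 1e-9, 60)
        vals = [nll(x) for x in taus]
        i = int(np.argmin(vals))
        res = minimize_scalar(
            nll,
            bounds=(taus[max(i - 1, 0)], taus[min(i + 1, len(taus) - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        tau = float(res.x) if res.fun < vals[i] else float(taus[i])
        _, coef, sigma = fit_at(k, m, tau)
        params = HMMParams(float(coef[0]), float(coef[1]), float(coef[2]), tau, sigma)
        ll = log_likelihood(params, series, max_td)
        if best is None or ll > best[0]:
            best = (ll, params, k)
    assert best is not None
    return best


def brute_force_knn_impute(scores: np.ndarray, k: int) -> np.ndarray:
    """Direct k-NN mean imputation with the package's distance convention.

    Distance = Euclidean over co-observed cells divided by the co-observed
    count; candidates must have the target cell observed; ties broken by
    lower row index (via stable sort on (distance, index) pairs).
    """
    out = scores.copy()
    n, p = scores.shape
    for i in range(n):
        for j in range(p):
            if not np.isnan(scores[i, j]):
                continue
            cands = []
            for c in range(n):
                if c == i or np.isnan(scores[c, j]):
                    continue
                co = ~np.isnan(scores[i]) & ~np.isnan(scores[c])
                if not co.any():
                    continue
                d = np.sqrt(np.sum((scores[i, co] - scores[c, co]) ** 2)) / co.sum()
                cands.append((d, c))
            cands.sort(key=lambda dc: (dc[0], dc[1]))
            out[i, j] = np.mean([scores[c, j] for _, c in cands[:k]])
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return float(num / den)
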