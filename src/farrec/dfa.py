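"""Dynamic Factor Analysis: one shared latent trend from a survey panel.

Model (single trend):

    x_t = x_{t-1} + w_t,   w_t ~ N(0, 1)        (process variance fixed at 1
                                                  for scale identifiability)
    y_it = Z_i x_t + v_it, v_it ~ N(0, r_i)      (diagonal R, unequal
                                                  variances, no covariance)

Estimation is EM with a Kalman filter/RTS smoother; missing observations
simply contribute nothing to the update step, which is what makes DFA robust
to gappy survey series.  The sign indeterminacy (Z, x) ~ (-Z, -x) is resolved
by requiring the mean loading to be non-negative.  Loading confidence
intervals come from the observed-information Hessian of the log-likelihood at
the MLE; the trend CI comes from the smoother variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

__all__ = ["DfaResult", "kalman_smoother", "kalman_loglik", "fit_dfa"]

logger = logging.getLogger(__name__)

_X0_VAR = 100.0  # weak prior variance on the initial state


@dataclass
class DfaResult:
    """Fitted single-trend DFA."""

    trend: pd.DataFrame  # year, estimate, lo95, hi95
    loadings: pd.DataFrame  # series_id, estimate, se, lo95, hi95
    obs_variance: pd.Series  # per-series r_i
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    dropped_series: list


@numba.njit(cache=True)
def _filter_pass(y, Z, R):
    """Univariate-processing Kalman filter for the scalar-state DFA.

    y is (n_years, n_series) with NaN for missing.  Returns filtered means and
    variances, one-step predictions, and the log-likelihood.
    """
    n, m = y.shape
    xf = np.empty(n)
    pf = np.empty(n)
    xp = np.empty(n)
    pp = np.empty(n)
    ll = 0.0
    x, p = 0.0, _X0_VAR
    for t in range(n):
        xp[t] = x
        pp[t] = p
        for i in range(m):
            obs = y[t, i]
            if np.isnan(obs):
                continue
            f = Z[i] * Z[i] * p + R[i]
            v = obs - Z[i] * x
            ll -= 0.5 * (np.log(2.0 * np.pi * f) + v * v / f)
            k = p * Z[i] / f
            x = x + k * v
            p = p - k * Z[i] * p
        xf[t] = x
        pf[t] = p
        p = p + 1.0  # process variance fixed at 1
    return xf, pf, xp, pp, ll


@numba.njit(cache=True)
def _smoother_pass(y, Z, R):
    n = y.shape[0]
    xf, pf, xp, pp, ll = _filter_pass(y, Z, R)
    xs = np.empty(n)
    ps = np.empty(n)
    xs[n - 1] = xf[n - 1]
    ps[n - 1] = pf[n - 1]
    for t in range(n - 2, -1, -1):
        j = pf[t] / (pf[t] + 1.0)
        xs[t] = xf[t] + j * (xs[t + 1] - xf[t])
        ps[t] = pf[t] + j * j * (ps[t + 1] - (pf[t] + 1.0))
    return xs, ps, ll


@numba.njit(cache=True)
def _em_core(y, Z0, R0, tol, max_iter):
    """EM iterations; returns (Z, R, loglik path, converged, monotone)."""
    n, m = y.shape
    Z = Z0.copy()
    R = R0.copy()
    ll_path = np.empty(max_iter)
    ll_prev = -np.inf
    converged = False
    monotone = True
    it = 0
    for it in range(max_iter):
        xs, ps, ll = _smoother_pass(y, Z, R)
        ll_path[it] = ll
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            monotone = False
            break
        for i in range(m):
            sxy = 0.0
            sxx = 0.0
            syy = 0.0
            cnt = 0
            for t in range(n):
                obs = y[t, i]
                if np.isnan(obs):
                    continue
                ex2 = xs[t] * xs[t] + ps[t]
                sxy += obs * xs[t]
                sxx += ex2
                syy += obs * obs
                cnt += 1
            zi = sxy / sxx
            Z[i] = zi
            resid = syy - 2.0 * zi * sxy + zi * zi * sxx
            R[i] = max(resid / cnt, 1e-8)
        if it > 0 and abs(ll - ll_prev) < tol * max(1.0, abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
    return Z, R, ll_path[: it + 1], converged, monotone


def kalman_loglik(y: np.ndarray, Z: np.ndarray, R: np.ndarray) -> float:
    """Exact Gaussian log-likelihood of the panel under the DFA model."""
    if np.any(R <= 0):
        raise ValueError("observation variances must be positive")
    return _filter_pass(y, Z, R)[4]


def kalman_smoother(y: np.ndarray, Z: np.ndarray, R: np.ndarray):
    """RTS smoother: E[x_t | all data] and Var[x_t | all data].

    Returns (smoothed mean, smoothed variance, log-likelihood).
    """
    if np.any(np.asarray(R) <= 0):
        raise ValueError("observation variances must be positive (non-PSD R)")
    return _smoother_pass(
        np.asarray(y, dtype=float), np.asarray(Z, dtype=float),
        np.asarray(R, dtype=float),
    )


def _moment_init(y: np.ndarray):
    """Loadings from covariance with the row-mean proxy trend, variances
    from residuals."""
    m = y.shape[1]
    obs_mask = ~np.isnan(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        proxy = np.nanmean(y, axis=1)  # all-missing years yield NaN
    proxy = np.where(np.isnan(proxy), 0.0, proxy)
    denom = np.sum(proxy**2) + 1e-12
    Z = np.array([
        np.nansum(y[:, i] * proxy) / denom if obs_mask[:, i].any() else 0.1
        for i in range(m)
    ])
    Z = np.where(np.abs(Z) < 1e-3, 0.1, Z)
    R = np.array([
        max(np.nanvar(y[:, i] - Z[i] * proxy), 1e-3) if obs_mask[:, i].any()
        else 1.0
        for i in range(m)
    ])
    return Z, R


def _em_fit(y: np.ndarray, tol: float, max_iter: int):
    Z0, R0 = _moment_init(y)
    Z, R, ll_path, converged, monotone = _em_core(y, Z0, R0, tol, max_iter)
    if not monotone:
        it = len(ll_path) - 1
        raise RuntimeError(
            f"EM log-likelihood decreased at iteration {it} "
            f"({ll_path[-2]:.6f} -> {ll_path[-1]:.6f}); this indicates a bug"
        )
    return Z, R, ll_path, converged


def _loading_ci(y: np.ndarray, Z: np.ndarray, R: np.ndarray):
    """Standard errors of loadings from the observed-information Hessian.

    Numerical Hessian of the negative log-likelihood in (Z, log R), inverted;
    the loading block of the inverse gives the loading covariance.
    """
    m = Z.size
    theta = np.concatenate([Z, np.log(R)])

    def nll(th):
        return -kalman_loglik(y, th[:m], np.exp(th[m:]))

    k = theta.size
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ti = theta.copy()
            if i == j:
                ti[i] += h[i]
                fp = nll(ti)
                ti[i] -= 2 * h[i]
                fm = nll(ti)
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)
                ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:m], 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fits
        logger.warning("singular Hessian; loading SEs set to NaN")
        se = np.full(m, np.nan)
    return se


def _ffbs_draw(y, Z, R, rng):
    """Forward-filter backward-sample: one trend path from p(x | y, theta)."""
    n = y.shape[0]
    xf, pf, xp, pp, _ = _filter_pass(y, Z, R)
    x = np.empty(n)
    x[-1] = rng.normal(xf[-1], np.sqrt(max(pf[-1], 1e-12)))
    for t in range(n - 2, -1, -1):
        j = pf[t] / (pf[t] + 1.0)
        mean = xf[t] + j * (x[t + 1] - xf[t])
        var = max(pf[t] * (1.0 - j), 1e-12)
        x[t] = rng.normal(mean, np.sqrt(var))
    return x


def _bootstrap_ci(y, Z, R, tol, max_iter, n_boot, seed):
    """Conditional parametric-bootstrap loading SEs and percentile CIs.

    Each draw samples a trend path from the smoothing posterior (FFBS), so
    the bootstrap conditions on the magnitude of the trend actually
    realized — effectively an ancillary for loading identification: a panel
    whose trend happened to wander little identifies loadings weakly, and an
    unconditional bootstrap (fresh random-walk trends) would understate that
    replicate's uncertainty.  Observations are regenerated from the fitted
    model along the sampled path, the missingness pattern is preserved, and
    the model is refit by EM; refitting per draw also captures the
    finite-sample amplification of loading variability that the
    observed-information Hessian misses for near-zero loadings.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, m = y.shape
    miss = np.isnan(y)
    draws = np.empty((n_boot, m))
    for b in range(n_boot):
        x = _ffbs_draw(y, Z, R, rng)
        yb = Z[None, :] * x[:, None] + rng.normal(0, 1, (n, m)) * np.sqrt(R)
        yb[miss] = np.nan
        Zb, _, _, _, _ = _em_core(yb, Z.copy(), R.copy(), tol, max_iter)
        if Zb.mean() < 0:
            Zb = -Zb
        draws[b] = Zb
    se = draws.std(axis=0, ddof=1)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    return se, lo, hi


def fit_dfa(
    panel: pd.DataFrame,
    n_trends: int = 1,
    *,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 5000,
    ci_method: str = "hessian",
    n_boot: int = 200,
    seed: int = 0,
) -> DfaResult:
    """Fit the single-trend DFA to a wide panel (year index, series columns).

    Each series may contain NaN for missing surveys.  With
    ``standardize=True`` (the convention for survey indices on disparate
    scales) every series is rescaled to zero mean, unit variance over its
    observed entries before fitting, so loadings are unitless.

    ``ci_method``: "hessian" (observed-information, fast, default) or
    "bootstrap" (parametric bootstrap with ``n_boot`` refits — preferable
    for short panels, where Hessian SEs understate the sampling variability
    of near-zero loadings).
    """
    if n_trends != 1:
        raise NotImplementedError("only the single shared trend is supported")
    panel = panel.copy()
    dropped = [c for c in panel.columns if panel[c].notna().sum() < 2]
    if dropped:
        logger.warning("dropping all-missing/underobserved series: %s", dropped)
        panel = panel.drop(columns=dropped)
    if panel.shape[1] < 2:
        raise ValueError("DFA needs at least 2 series with >= 2 observations")
    if standardize:
        panel = (panel - panel.mean()) / panel.std(ddof=1)
    y = panel.to_numpy(dtype=float)

    Z, R, ll_path, converged = _em_fit(y, tol, max_iter)
    if not converged:
        logger.warning("EM reached max_iter=%d without converging", max_iter)

    # Sign convention: mean loading >= 0 (likelihood is invariant to the
    # joint flip (Z, x) -> (-Z, -x); the smoother below returns the trend on
    # the flipped scale automatically).
    if Z.mean() < 0:
        Z = -Z
    xs, ps, ll = kalman_smoother(y, Z, R)

    zcrit = 1.959963984540054
    if ci_method == "bootstrap":
        se, lo95, hi95 = _bootstrap_ci(y, Z, R, tol, max_iter, n_boot, seed)
    elif ci_method == "hessian":
        se = _loading_ci(y, Z, R)
        lo95, hi95 = Z - zcrit * se, Z + zcrit * se
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    loadings = pd.DataFrame(
        {
            "series_id": panel.columns,
            "estimate": Z,
            "se": se,
            "lo95": lo95,
            "hi95": hi95,
        }
    )
    trend = pd.DataFrame(
        {
            "year": panel.index.to_numpy(),
            "estimate": xs,
            "lo95": xs - zcrit * np.sqrt(ps),
            "hi95": xs + zcrit * np.sqrt(ps),
        }
    )
    return DfaResult(
        trend=trend,
        loadings=loadings,
        obs_variance=pd.Series(R, index=panel.columns, name="obs_variance"),
        loglik=float(ll),
        loglik_path=ll_path,
        n_iter=len(ll_path),
        converged=converged,
        dropped_series=dropped,
    )
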