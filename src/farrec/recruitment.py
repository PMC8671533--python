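"""Recruitment-FAR response models.

Standardized log recruitment anomalies (zero mean, unit variance) are modeled
as a penalized thin-plate spline function of FAR, optionally with a second
smooth for spawning stock biomass.  Two variants:

* error-free: the per-year FAR posterior mean is treated as known;
* measurement-error: each year's true FAR is latent, with a truncated-Normal
  prior centered on the posterior mean with SD equal to the posterior SE from
  the beta ensemble model.  The spline is applied to the latent FAR, which
  propagates attribution uncertainty into the recruitment response (and into
  projections built from it).

Model comparison is by LOOIC (−2 × PSIS-LOO elpd); fit quality is summarized
by Bayesian R² (per-draw fitted-variance / (fitted + residual variance)).
The two-step bridge estimating recent recruitment from the seine index is
ordinary linear regression on the overlap years with closed-form predictive
standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .mcmc import ParamSpec, HmcResult, check_convergence, sample_hmc
from .splines import ThinPlateBasis

__all__ = [
    "RecruitFit",
    "fit_far_gam",
    "fit_far_gam_me",
    "loo_compare",
    "bayes_r2",
    "classify_failure",
    "bridge_recent_recruitment",
]

logger = logging.getLogger(__name__)

_PRIOR_SD_NULL = 10.0  # null-space (intercept, linear) coefficients
_PRIOR_SD_TAU = 1.0  # half-Normal scale for smoothing SD
_PRIOR_SD_SIGMA = 1.0  # half-Normal scale for residual SD


@dataclass
class RecruitFit:
    """Posterior spline fit of recruitment on FAR."""

    draws: HmcResult = field(repr=False)
    basis: ThinPlateBasis
    x: np.ndarray  # FAR covariate (posterior means)
    y: np.ndarray  # standardized log recruitment anomalies
    years: np.ndarray
    k: int
    measurement_error: bool = False
    far_se: np.ndarray | None = None
    ssb_basis: ThinPlateBasis | None = None
    ssb: np.ndarray | None = None
    convergence: object = None

    # -- posterior accessors -------------------------------------------------
    def coef_draws(self) -> np.ndarray:
        return self.draws.get("beta")

    def sigma_draws(self) -> np.ndarray:
        return np.exp(self.draws.get("log_sigma")[:, 0])

    def latent_far_draws(self) -> np.ndarray:
        if not self.measurement_error:
            raise ValueError("latent FAR exists only in the measurement-error fit")
        return expit(self.draws.get("f_raw"))

    def fitted_draws(self) -> np.ndarray:
        """Fitted mean for each observation, per draw: (n_draws, n_obs)."""
        beta = self.coef_draws()
        if self.measurement_error:
            far = self.latent_far_draws()  # (S, n)
            fitted = np.empty_like(far)
            for s in range(far.shape[0]):
                fitted[s] = self.basis.design(far[s]) @ beta[s, : self.k]
        else:
            fitted = beta[:, : self.k] @ self.basis.design(self.x).T
        if self.ssb_basis is not None:
            fitted = fitted + beta[:, self.k:] @ self._ssb_design().T
        return fitted

    def _ssb_design(self) -> np.ndarray:
        # drop the duplicate intercept column of the second smooth
        return self.ssb_basis.design(self.ssb)[:, 1:]

    def predict_curve(self, far_grid: np.ndarray) -> np.ndarray:
        """Draws of the mean response at the given FAR values: (S, m).

        With an SSB smooth present, SSB is held at its sample mean (where the
        centered smooth contributes approximately zero).
        """
        X = self.basis.design(np.asarray(far_grid, dtype=float))
        curves = self.coef_draws()[:, : self.k] @ X.T
        if self.ssb_basis is not None:
            x0 = self.ssb_basis.design(np.array([np.mean(self.ssb)]))[:, 1:]
            curves = curves + self.coef_draws()[:, self.k:] @ x0.T
        return curves

    def pointwise_loglik(self) -> np.ndarray:
        """(n_chains, n_draws, n_obs) Gaussian log-likelihoods for LOO."""
        nc, nd = self.draws.n_chains, self.draws.n_draws
        fitted = self.fitted_draws().reshape(nc, nd, -1)
        sigma = self.sigma_draws().reshape(nc, nd, 1)
        resid = self.y[None, None, :] - fitted
        return (
            -0.5 * np.log(2.0 * np.pi * sigma**2) - 0.5 * (resid / sigma) ** 2
        )

    def loo(self):
        """PSIS-LOO via arviz; returns the ELPDData object."""
        import arviz as az

        ll = self.pointwise_loglik()
        idata = az.from_dict(
            posterior={"sigma": self.sigma_draws().reshape(ll.shape[:2])},
            log_likelihood={"y": ll},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(idata, pointwise=True)

    @property
    def looic(self) -> float:
        return float(-2.0 * self.loo().elpd_loo)


def _make_gam_logp(y, basis, x, ssb_basis=None, ssb=None):
    X = basis.design(x)
    k = X.shape[1]
    if ssb_basis is not None:
        X = np.column_stack([X, ssb_basis.design(ssb)[:, 1:]])
    p = X.shape[1]
    pen = np.zeros(p, dtype=bool)
    pen[2:k] = True
    if ssb_basis is not None:
        pen[k + 1:] = True  # ssb smooth: [linear, penalized...]; linear unpenalized
    spec = ParamSpec({"beta": p, "log_tau": 1, "log_sigma": 1})
    n = y.size

    def logp_grad(theta):
        pr = spec.unpack(theta)
        beta = pr["beta"]
        log_tau, log_sigma = pr["log_tau"][0], pr["log_sigma"][0]
        if abs(log_tau) > 15 or abs(log_sigma) > 15:
            return -np.inf, np.zeros_like(theta)
        tau, sigma = np.exp(log_tau), np.exp(log_sigma)
        resid = y - X @ beta
        lp = -n * log_sigma - 0.5 * np.sum(resid**2) / sigma**2
        g_beta = X.T @ resid / sigma**2
        g_log_sigma = -n + np.sum(resid**2) / sigma**2
        # priors
        lp += -0.5 * np.sum(beta[~pen] ** 2) / _PRIOR_SD_NULL**2
        g_beta[~pen] += -beta[~pen] / _PRIOR_SD_NULL**2
        npen = int(pen.sum())
        lp += -npen * log_tau - 0.5 * np.sum(beta[pen] ** 2) / tau**2
        g_beta[pen] += -beta[pen] / tau**2
        g_log_tau = -npen + np.sum(beta[pen] ** 2) / tau**2
        lp += -0.5 * tau**2 / _PRIOR_SD_TAU**2 + log_tau
        g_log_tau += -(tau**2) / _PRIOR_SD_TAU**2 + 1.0
        lp += -0.5 * sigma**2 / _PRIOR_SD_SIGMA**2 + log_sigma
        g_log_sigma += -(sigma**2) / _PRIOR_SD_SIGMA**2 + 1.0
        return lp, np.concatenate([g_beta, [g_log_tau], [g_log_sigma]])

    return logp_grad, spec, X


def fit_far_gam(
    recruitment: pd.Series,
    far: pd.Series | np.ndarray,
    *,
    ssb: pd.Series | np.ndarray | None = None,
    k: int = 3,
    n_chains: int = 2,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
) -> RecruitFit:
    """Penalized spline of standardized log recruitment on FAR (error-free).

    ``recruitment`` and ``far`` must be aligned by year (shared index if both
    are Series).  k is the total number of basis functions (3 or 5 by the
    study's convention).
    """
    if isinstance(recruitment, pd.Series) and isinstance(far, pd.Series):
        common = recruitment.index.intersection(far.index)
        recruitment = recruitment.loc[common]
        far = far.loc[common]
    y = np.asarray(recruitment, dtype=float)
    x = np.asarray(far, dtype=float)
    years = (
        recruitment.index.to_numpy()
        if isinstance(recruitment, pd.Series)
        else np.arange(y.size)
    )
    if y.size != x.size:
        raise ValueError("recruitment and FAR series must align")
    if k > y.size - 2:
        raise ValueError(f"k={k} requires more than {k + 2} observations")
    basis = ThinPlateBasis(x, k)
    ssb_basis = None
    ssb_arr = None
    if ssb is not None:
        ssb_arr = np.asarray(ssb, dtype=float)
        ssb_basis = ThinPlateBasis(ssb_arr, k)
    logp_grad, spec, X = _make_gam_logp(y, basis, x, ssb_basis, ssb_arr)
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    init = spec.pack(beta=beta0, log_tau=np.log(0.5), log_sigma=np.log(0.5))
    res = sample_hmc(
        logp_grad, init, spec,
        n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws, seed=seed,
        init_jitter=0.1,
    )
    conv = check_convergence(res.draws, n_divergent=res.n_divergent)
    if not conv.passed:
        logger.warning("FAR spline model convergence check failed: %r", conv)
    return RecruitFit(
        draws=res, basis=basis, x=x, y=y, years=years, k=k,
        ssb_basis=ssb_basis, ssb=ssb_arr, convergence=conv,
    )


def _make_gam_me_logp(y, basis, far_mean, far_se, k):
    n = y.size
    spec = ParamSpec({"beta": k, "log_tau": 1, "log_sigma": 1, "f_raw": n})
    pen = np.zeros(k, dtype=bool)
    pen[2:] = True

    def logp_grad(theta):
        pr = spec.unpack(theta)
        beta, f_raw = pr["beta"], pr["f_raw"]
        log_tau, log_sigma = pr["log_tau"][0], pr["log_sigma"][0]
        if abs(log_tau) > 15 or abs(log_sigma) > 15 or np.any(np.abs(f_raw) > 30):
            return -np.inf, np.zeros_like(theta)
        tau, sigma = np.exp(log_tau), np.exp(log_sigma)
        far = expit(f_raw)
        X = basis.design(far)
        resid = y - X @ beta
        lp = -n * log_sigma - 0.5 * np.sum(resid**2) / sigma**2
        g_beta = X.T @ resid / sigma**2
        g_log_sigma = -n + np.sum(resid**2) / sigma**2
        # gradient through the latent covariate
        dX = basis.design_grad(far)
        dfar = far * (1.0 - far)
        g_f = (resid / sigma**2) * (dX @ beta) * dfar
        # truncated-Normal(far_mean, far_se) prior on latent FAR in (0,1);
        # the truncation constant does not depend on parameters.  Logistic
        # transform Jacobian keeps draws interior.
        zse = (far - far_mean) / far_se
        lp += -0.5 * np.sum(zse**2) + np.sum(log_expit(f_raw) + log_expit(-f_raw))
        g_f += -(zse / far_se) * dfar + (1.0 - 2.0 * far)
        # coefficient priors (as in the error-free model)
        lp += -0.5 * np.sum(beta[~pen] ** 2) / _PRIOR_SD_NULL**2
        g_beta[~pen] += -beta[~pen] / _PRIOR_SD_NULL**2
        npen = int(pen.sum())
        lp += -npen * log_tau - 0.5 * np.sum(beta[pen] ** 2) / tau**2
        g_beta[pen] += -beta[pen] / tau**2
        g_log_tau = -npen + np.sum(beta[pen] ** 2) / tau**2
        lp += -0.5 * tau**2 / _PRIOR_SD_TAU**2 + log_tau
        g_log_tau += -(tau**2) / _PRIOR_SD_TAU**2 + 1.0
        lp += -0.5 * sigma**2 / _PRIOR_SD_SIGMA**2 + log_sigma
        g_log_sigma += -(sigma**2) / _PRIOR_SD_SIGMA**2 + 1.0
        grad = np.concatenate([g_beta, [g_log_tau], [g_log_sigma], g_f])
        return lp, grad

    return logp_grad, spec


def fit_far_gam_me(
    recruitment: pd.Series,
    far_mean: pd.Series | np.ndarray,
    far_se: pd.Series | np.ndarray,
    *,
    k: int = 3,
    n_chains: int = 2,
    n_warmup: int = 600,
    n_draws: int = 600,
    seed: int = 0,
) -> RecruitFit:
    """Spline of recruitment on latent FAR with measurement error.

    Each year's true FAR is latent with a truncated-Normal(far_mean, far_se)
    prior on (0, 1).  With all SEs zero the latent layer is degenerate and the
    error-free model is fit instead (with a notice).
    """
    if isinstance(recruitment, pd.Series) and isinstance(far_mean, pd.Series):
        common = recruitment.index.intersection(far_mean.index)
        recruitment = recruitment.loc[common]
        far_mean = far_mean.loc[common]
        if isinstance(far_se, pd.Series):
            far_se = far_se.loc[common]
    y = np.asarray(recruitment, dtype=float)
    m = np.asarray(far_mean, dtype=float)
    se = np.asarray(far_se, dtype=float)
    years = (
        recruitment.index.to_numpy()
        if isinstance(recruitment, pd.Series)
        else np.arange(y.size)
    )
    if np.any(se < 0):
        raise ValueError("far_se must be non-negative")
    if np.all(se == 0):
        logger.warning("all FAR SEs are zero; falling back to the error-free fit")
        fit = fit_far_gam(
            pd.Series(y, index=years), pd.Series(m, index=years), k=k,
            n_chains=2, seed=seed,
        )
        return fit
    se = np.clip(se, 1e-4, None)
    if k > y.size - 2:
        raise ValueError(f"k={k} requires more than {k + 2} observations")
    # knots fixed at the FAR posterior means
    basis = ThinPlateBasis(m, k)
    logp_grad, spec = _make_gam_me_logp(y, basis, m, se, k)
    X0 = basis.design(m)
    beta0 = np.linalg.lstsq(X0, y, rcond=None)[0]
    m_clip = np.clip(m, 1e-4, 1 - 1e-4)
    init = spec.pack(
        beta=beta0, log_tau=np.log(0.5), log_sigma=np.log(0.5),
        f_raw=np.log(m_clip / (1 - m_clip)),
    )
    # rough posterior scales: latent logit-FAR scale is se / (m(1-m))
    f_scale = np.clip(se / np.clip(m_clip * (1 - m_clip), 1e-3, None), 1e-3, 3.0)
    scales = spec.pack(
        beta=np.full(k, 0.5), log_tau=0.5, log_sigma=0.3, f_raw=f_scale
    )
    res = sample_hmc(
        logp_grad, init, spec,
        n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws, seed=seed,
        init_jitter=0.1, max_leapfrog=48, init_scales=scales,
    )
    conv = check_convergence(res.draws, n_divergent=res.n_divergent)
    if not conv.passed:
        logger.warning("measurement-error spline convergence check failed: %r", conv)
    return RecruitFit(
        draws=res, basis=basis, x=m, y=y, years=years, k=k,
        measurement_error=True, far_se=se, convergence=conv,
    )


def loo_compare(fits: dict[str, object]) -> pd.DataFrame:
    """LOOIC comparison table across fits of the same observations.

    Accepts any objects exposing ``pointwise_loglik()`` (shape chains x draws
    x observations).  Returns a DataFrame sorted by LOOIC with Δ-LOOIC
    relative to the best model and Pareto-k diagnostics (k > 0.7 flagged).
    """
    import arviz as az

    rows = []
    n_obs = None
    for name, fit in fits.items():
        ll = fit.pointwise_loglik()
        if n_obs is None:
            n_obs = ll.shape[-1]
        elif ll.shape[-1] != n_obs:
            raise ValueError(
                f"fit {name!r} has {ll.shape[-1]} observations, expected {n_obs}"
            )
        idata = az.from_dict(
            posterior={"lp": ll.sum(axis=-1)},
            log_likelihood={"y": ll},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(idata, pointwise=True)
        k_vals = np.asarray(res.pareto_k)
        rows.append(
            {
                "model": name,
                "elpd_loo": float(res.elpd_loo),
                "se": float(res.se),
                "looic": float(-2.0 * res.elpd_loo),
                "p_loo": float(res.p_loo),
                "n_high_pareto_k": int(np.sum(k_vals > 0.7)),
            }
        )
    table = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)
    table["delta_looic"] = table["looic"] - table["looic"].min()
    if (table["n_high_pareto_k"] > 0).any():
        logger.warning("some Pareto-k diagnostics exceed 0.7; PSIS-LOO unreliable")
    return table


def bayes_r2(fit) -> dict:
    """Posterior Bayesian R²: per-draw var(fitted)/(var(fitted)+var(resid)).

    Residual variance is the model's residual variance parameter per draw.
    Returns median and 95% CI with the draw vector.
    """
    fitted = fit.fitted_draws()
    if fitted.shape[0] < 2:
        raise ValueError("Bayesian R² needs more than one posterior draw")
    var_fit = fitted.var(axis=1, ddof=1)
    sigma2 = fit.sigma_draws() ** 2
    r2 = var_fit / (var_fit + sigma2)
    lo, hi = np.quantile(r2, [0.025, 0.975])
    return {
        "median": float(np.median(r2)),
        "ci95_lo": float(lo),
        "ci95_hi": float(hi),
        "draws": r2,
    }


def classify_failure(log_anomaly) -> np.ndarray | bool:
    """Recruitment failure: standardized log anomaly strictly below -1."""
    arr = np.asarray(log_anomaly, dtype=float)
    out = arr < -1.0
    return bool(out) if out.ndim == 0 else out


def bridge_recent_recruitment(
    seine_index: pd.Series,
    assessment: pd.Series,
    overlap: tuple[int, int],
    predict_years: list[int],
) -> pd.DataFrame:
    """Predict recent recruitment from the seine index by linear regression.

    Fits OLS of assessment recruitment on the (log) seine index over the
    overlap years only, then predicts the requested years with closed-form
    predictive standard errors.  Returns a DataFrame (year, prediction, se,
    source='seine_bridge').
    """
    import statsmodels.api as sm

    years = np.arange(overlap[0], overlap[1] + 1)
    years = [y for y in years if y in seine_index.index and y in assessment.index]
    if len(years) < 3:
        raise ValueError(f"need >= 3 overlap years, got {len(years)}")
    if set(predict_years) & set(years):
        raise ValueError("predict_years must be disjoint from the overlap window")
    missing = [y for y in predict_years if y not in seine_index.index]
    if missing:
        raise ValueError(f"seine index missing for predict years {missing}")
    X = sm.add_constant(seine_index.loc[years].to_numpy(dtype=float))
    fit = sm.OLS(assessment.loc[years].to_numpy(dtype=float), X).fit()
    Xnew = sm.add_constant(
        seine_index.loc[list(predict_years)].to_numpy(dtype=float),
        has_constant="add",
    )
    pred = fit.get_prediction(Xnew)
    return pd.DataFrame(
        {
            "year": list(predict_years),
            "prediction": pred.predicted_mean,
            "se": pred.se_obs,
            "source": "seine_bridge",
        }
    )
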