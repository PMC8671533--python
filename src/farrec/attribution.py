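"""Extreme-event attribution: exceedance probabilities and FAR.

The Fraction of Attributable Risk for a climate anomaly is

    FAR = 1 - P(anomaly | preindustrial) / P(anomaly | current),

with each probability measured empirically as the proportion of anomalies in
the reference sample greater than or equal to the focal anomaly.  FAR
estimates the share of the event's risk attributable to human influence;
values near 1 mark anomalies effectively impossible under preindustrial
(natural) variability.

Per-year, per-model FAR values from a climate ensemble are combined with a
Bayesian beta regression: logit-linear year fixed effects, climate-model
identity as a random effect, shared precision.  Because beta support excludes
the endpoints, raw FAR of 1 is reset to 0.9999 and FAR <= 0 to 0.0001 before
fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from .mcmc import ParamSpec, HmcResult, check_convergence, sample_hmc

__all__ = [
    "ModelRealizations",
    "ClimateEnsemble",
    "FarEstimate",
    "standardize_anomalies",
    "exceedance_probability",
    "compute_far",
    "build_far_table",
    "fit_far_model",
]

logger = logging.getLogger(__name__)

CLAMP_LO = 1e-4
CLAMP_HI = 0.9999


@dataclass
class ModelRealizations:
    """One climate model's preindustrial and scenario-projection series."""

    model_id: str
    preindustrial: pd.Series  # anomaly values; index ignored for sampling
    projection: pd.Series  # indexed by calendar year

    def __post_init__(self):
        if len(self.preindustrial) < 2:
            raise ValueError(
                f"model {self.model_id}: preindustrial realization needs >= 2 values"
            )


@dataclass
class ClimateEnsemble:
    """Observed anomaly series plus per-model realizations."""

    observed: pd.Series  # indexed by calendar year
    models: list[ModelRealizations]

    def __post_init__(self):
        if len(self.models) == 0:
            raise ValueError("ensemble needs at least one climate model")
        years = np.asarray(self.observed.index)
        if not np.all(np.diff(years) > 0):
            raise ValueError("observed years must be strictly increasing")
        if not np.all(np.isfinite(self.observed.to_numpy(dtype=float))):
            raise ValueError("observed anomalies must be finite")

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]


def standardize_anomalies(
    raw: pd.Series,
    center_window: tuple[int, int],
    scale_window: tuple[int, int],
) -> pd.Series:
    """Standardize a raw annual series to anomalies.

    value -> (value - mean over center_window) / SD over scale_window.
    Windows are inclusive (start_year, end_year) ranges on the index.
    """
    years = raw.index.to_numpy()
    c_mask = (years >= center_window[0]) & (years <= center_window[1])
    s_mask = (years >= scale_window[0]) & (years <= scale_window[1])
    if not c_mask.any():
        raise ValueError(f"center window {center_window} does not overlap the series")
    if not s_mask.any():
        raise ValueError(f"scale window {scale_window} does not overlap the series")
    center = raw[c_mask].mean()
    sd = raw[s_mask].std(ddof=1)
    if not sd > 0:
        raise ValueError(f"scale window {scale_window} has zero SD")
    return (raw - center) / sd


def exceedance_probability(anomaly: float, sample: np.ndarray) -> float:
    """Proportion of the sample greater than or equal to the focal anomaly."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty reference sample")
    return float(np.count_nonzero(sample >= anomaly)) / sample.size


def compute_far(
    anomaly: float,
    preindustrial_sample: np.ndarray,
    current_sample: np.ndarray,
    clamp_lo: float = CLAMP_LO,
    clamp_hi: float = CLAMP_HI,
) -> float:
    """FAR = 1 - p_pre / p_cur with empirical exceedance probabilities.

    The result is clamped into [clamp_lo, clamp_hi] so it is admissible for
    the beta ensemble model (raw FAR of exactly 1 becomes 0.9999; raw FAR
    <= 0, i.e. the anomaly no rarer now than preindustrially, becomes
    clamp_lo).
    """
    p_pre = exceedance_probability(anomaly, preindustrial_sample)
    p_cur = exceedance_probability(anomaly, current_sample)
    if p_cur == 0.0:
        raise ValueError(
            "current-sample exceedance probability is 0; include the focal "
            "year in its own reference sample so p_cur >= 1/n"
        )
    raw = 1.0 - p_pre / p_cur
    if raw < clamp_lo or raw > clamp_hi:
        logger.debug("FAR %.4f clamped into [%g, %g]", raw, clamp_lo, clamp_hi)
    return float(np.clip(raw, clamp_lo, clamp_hi))


def build_far_table(
    ensemble: ClimateEnsemble,
    period: str = "hindcast",
    clamp_lo: float = CLAMP_LO,
    clamp_hi: float = CLAMP_HI,
) -> pd.DataFrame:
    """Per-year, per-model FAR rows.

    hindcast: the focal anomaly and the "current" sample are the observed
    series; projection: each model's projection realization supplies both.
    The preindustrial exceedance probability is always computed against that
    model's own preindustrial realization.
    """
    if period not in ("hindcast", "projection"):
        raise ValueError(f"unknown period {period!r}")
    rows = []
    for m in ensemble.models:
        pre = m.preindustrial.to_numpy(dtype=float)
        if period == "hindcast":
            focal = ensemble.observed
            current = ensemble.observed.to_numpy(dtype=float)
        else:
            if m.projection is None or len(m.projection) == 0:
                raise ValueError(f"model {m.model_id} has no projection realization")
            focal = m.projection
            current = m.projection.to_numpy(dtype=float)
        for year, anom in focal.items():
            p_pre = exceedance_probability(anom, pre)
            p_cur = exceedance_probability(anom, current)
            far = compute_far(anom, pre, current, clamp_lo, clamp_hi)
            rows.append(
                {"year": int(year), "model_id": m.model_id, "far": far,
                 "p_pre": p_pre, "p_cur": p_cur}
            )
    table = pd.DataFrame(rows)
    raw = 1.0 - table["p_pre"] / table["p_cur"]
    n_clamped = int(((raw < clamp_lo) | (raw > clamp_hi)).sum())
    if n_clamped:
        logger.warning(
            "%s FAR table: %d of %d values clamped into [%g, %g]",
            period, n_clamped, len(table), clamp_lo, clamp_hi,
        )
    return table


# ---------------------------------------------------------------------------
# Bayesian beta ensemble model
# ---------------------------------------------------------------------------

_PRIOR_SD_YEAR = 3.0  # Normal prior SD for logit-scale year effects
_PRIOR_SD_RE = 1.0  # half-Normal scale for the model random-effect SD
_PRIOR_SD_PHI = 50.0  # half-Normal scale for the beta precision


@dataclass
class FarEstimate:
    """Posterior per-year FAR summary from the beta ensemble model."""

    table: pd.DataFrame  # year, mean, se, ci80/90/95 lo+hi columns
    convergence: object = None
    draws: HmcResult | None = field(default=None, repr=False)

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def year_draws(self) -> np.ndarray:
        """Posterior draws of the per-year mean FAR, shape (n_draw, n_years)."""
        return expit(self.draws.get("alpha"))


def _beta_logp_grad_factory(y, year_idx, model_idx, n_years, n_models,
                            prior_sd_year=_PRIOR_SD_YEAR):
    """Log posterior and gradient for the beta year-effect model.

    Parameters (unconstrained): alpha (n_years logit-scale year effects),
    z (n_models standardized random effects), log_sigma, log_phi.
    mu = expit(alpha[year] + sigma * (z[model] - mean(z)));
    y ~ Beta(mu*phi, (1-mu)*phi).

    The model effects are centered within the predictor: with a handful of
    climate models a free random-effect mean is confounded with the year
    effects, and the effect's role is the between-model spread only.
    """
    y = np.asarray(y, dtype=float)
    log_y = np.log(y)
    log_1my = np.log1p(-y)
    spec = ParamSpec({"alpha": n_years, "z": n_models, "log_sigma": 1, "log_phi": 1})

    def logp_grad(theta):
        p = spec.unpack(theta)
        alpha, z = p["alpha"], p["z"]
        log_sigma = p["log_sigma"][0]
        log_phi = p["log_phi"][0]
        if abs(log_sigma) > 20 or abs(log_phi) > 20:
            return -np.inf, np.zeros_like(theta)
        sigma = np.exp(log_sigma)
        phi = np.exp(log_phi)
        zc = z - z.mean()
        eta = alpha[year_idx] + sigma * zc[model_idx]
        if np.max(np.abs(eta)) > 30.0:  # mu would saturate in float64
            return -np.inf, np.zeros_like(theta)
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * log_y + (b - 1.0) * log_1my
        )
        # gradient pieces
        dl_dmu = phi * (-digamma(a) + digamma(b) + log_y - log_1my)
        g_eta = dl_dmu * mu * (1.0 - mu)
        dl_dphi_i = (
            digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b)
            + mu * log_y + (1.0 - mu) * log_1my
        )
        g_alpha = np.bincount(year_idx, weights=g_eta, minlength=n_years)
        g_eta_by_model = np.bincount(model_idx, weights=g_eta,
                                     minlength=n_models)
        g_z = sigma * (g_eta_by_model - g_eta_by_model.sum() / n_models)
        g_log_sigma = sigma * np.sum(zc[model_idx] * g_eta)
        g_log_phi = phi * np.sum(dl_dphi_i)
        # priors
        lp = ll
        lp += -0.5 * np.sum(alpha**2) / prior_sd_year**2
        g_alpha += -alpha / prior_sd_year**2
        lp += -0.5 * np.sum(z**2)
        g_z += -z
        # sigma ~ halfNormal(_PRIOR_SD_RE), sampled on log scale (+ Jacobian)
        lp += -0.5 * sigma**2 / _PRIOR_SD_RE**2 + log_sigma
        g_log_sigma += -(sigma**2) / _PRIOR_SD_RE**2 + 1.0
        # phi ~ halfNormal(_PRIOR_SD_PHI) on natural scale (+ Jacobian)
        lp += -0.5 * phi**2 / _PRIOR_SD_PHI**2 + log_phi
        g_log_phi += -(phi**2) / _PRIOR_SD_PHI**2 + 1.0
        grad = np.concatenate([g_alpha, g_z, [g_log_sigma], [g_log_phi]])
        return lp, grad

    return logp_grad, spec


def fit_far_model(
    table: pd.DataFrame,
    *,
    n_chains: int = 2,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
    levels=(0.8, 0.9, 0.95),
) -> FarEstimate:
    """Fit the Bayesian beta ensemble model to a per-year-per-model FAR table.

    Returns per-year posterior mean, SE (posterior SD of the year mean), and
    equal-tailed 80/90/95% credible intervals for the year mean FAR (the
    model random effect marginalized at zero).
    """
    far = table["far"].to_numpy(dtype=float)
    if np.any(far <= 0.0) or np.any(far >= 1.0):
        raise ValueError(
            "FAR values must lie strictly in (0, 1); apply the clamping in "
            "compute_far/build_far_table before fitting"
        )
    years = np.sort(table["year"].unique())
    models = np.sort(table["model_id"].unique())
    if len(models) < 2:
        logger.warning("single climate model: random-effect SD weakly identified")
    year_idx = pd.Categorical(table["year"], categories=years).codes.astype(int)
    model_idx = pd.Categorical(table["model_id"], categories=models).codes.astype(int)

    logp_grad, spec = _beta_logp_grad_factory(
        far, year_idx, model_idx, len(years), len(models)
    )
    # Initialize year effects at empirical logits, hyperparameters modestly.
    emp = np.clip(
        pd.Series(far).groupby(year_idx).mean().reindex(range(len(years))).to_numpy(),
        1e-3, 1 - 1e-3,
    )
    init = spec.pack(
        alpha=np.log(emp / (1 - emp)),
        z=np.zeros(len(models)),
        log_sigma=np.log(0.3),
        log_phi=np.log(10.0),
    )
    res = sample_hmc(
        logp_grad, init, spec,
        n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws, seed=seed,
    )
    conv = check_convergence(res.draws, n_divergent=res.n_divergent)
    if not conv.passed:
        logger.warning("FAR beta model convergence check failed: %r", conv)

    mu_draws = expit(res.get("alpha"))  # (n_total_draws, n_years)
    rows = []
    for j, year in enumerate(years):
        d = mu_draws[:, j]
        row = {"year": int(year), "mean": float(d.mean()), "se": float(d.std(ddof=1))}
        for lev in levels:
            a = (1 - lev) / 2
            lo, hi = np.quantile(d, [a, 1 - a])
            row[f"ci{int(lev * 100)}_lo"] = float(lo)
            row[f"ci{int(lev * 100)}_hi"] = float(hi)
        rows.append(row)
    return FarEstimate(table=pd.DataFrame(rows), convergence=conv, draws=res)
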