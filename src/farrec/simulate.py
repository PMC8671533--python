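"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes, so each downstream stage is
testable without any external download:

* a climate ensemble — a trended AR(1) observed anomaly series plus, per
  pseudo-model, one stationary preindustrial realization and one trended
  projection realization (mirroring the one-realization-per-model design of
  downscaled CMIP5 output);
* annual log-recruitment anomalies whose mean declines with FAR, either
  linearly or as a step at a threshold (default 0.98);
* set-level beach-seine catches from a zero-inflated negative binomial with
  nested bay/site random intercepts;
* a multi-survey index panel sharing one latent trend with heterogeneous
  observation noise and missing-completely-at-random gaps.

One global seed expands to independent per-stream substreams via
``numpy.random.SeedSequence``, so adding a generator does not perturb others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import ClimateEnsemble, ModelRealizations

__all__ = [
    "ClimateSimParams",
    "RecruitSimParams",
    "SeineSimParams",
    "simulate_climate",
    "simulate_recruitment",
    "simulate_seine",
    "simulate_survey_panel",
    "write_simulation",
]


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value}")


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1): x_1 drawn from the stationary distribution."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


@dataclass
class ClimateSimParams:
    """Generative settings for the synthetic climate ensemble.

    Units: trends in anomaly units per year, noise_sd in anomaly units.
    Defaults mirror the study design: five pseudo-models, single 60-year
    preindustrial and projection realizations each.
    """

    n_years_obs: int = 60
    trend_obs: float = 0.05
    ar1_coef: float = 0.5
    noise_sd: float = 0.4
    n_models: int = 5
    n_years_pi: int = 60
    n_years_proj: int = 41
    trend_proj: float = 0.06
    seed: int = 0
    start_year_obs: int = 1961
    start_year_proj: int = 2006

    def __post_init__(self):
        for name in ("trend_obs", "ar1_coef", "noise_sd", "trend_proj"):
            _check_finite(name, getattr(self, name))
        if self.n_years_pi < 2:
            raise ValueError("n_years_pi must be >= 2")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("ar1_coef must satisfy |ar1_coef| < 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


def simulate_climate(params: ClimateSimParams) -> ClimateEnsemble:
    """Draw a synthetic climate ensemble.

    Observed series: linear trend (centered on the midpoint year) + stationary
    AR(1) noise.  Preindustrial realizations: stationary AR(1), no trend.
    Projections: shared linear trend + model-specific AR(1) noise, anchored so
    the trend continues from the observed period's end level.
    """
    ss = np.random.SeedSequence(params.seed)
    obs_seed, *model_seeds = ss.spawn(1 + params.n_models)

    rng = np.random.default_rng(obs_seed)
    t_obs = np.arange(params.n_years_obs, dtype=float)
    t_obs -= t_obs.mean()
    obs_vals = params.trend_obs * t_obs + _ar1(
        rng, params.n_years_obs, params.ar1_coef, params.noise_sd
    )
    obs_years = params.start_year_obs + np.arange(params.n_years_obs)
    observed = pd.Series(obs_vals, index=obs_years, name="observed")

    # Projection trend continues from the observed trend line at the
    # projection start year (the scenario overlaps the observed period, so
    # its early years still overlap natural variability).
    offset = params.start_year_proj - params.start_year_obs
    end_level = params.trend_obs * (offset - (params.n_years_obs - 1) / 2.0)
    models = []
    for i, mseed in enumerate(model_seeds):
        mrng = np.random.default_rng(mseed)
        pre = _ar1(mrng, params.n_years_pi, params.ar1_coef, params.noise_sd)
        t_proj = np.arange(params.n_years_proj, dtype=float)
        proj_vals = (
            end_level
            + params.trend_proj * t_proj
            + _ar1(mrng, params.n_years_proj, params.ar1_coef, params.noise_sd)
        )
        proj_years = params.start_year_proj + np.arange(params.n_years_proj)
        models.append(
            ModelRealizations(
                model_id=f"model_{i + 1}",
                preindustrial=pd.Series(pre, name="preindustrial"),
                projection=pd.Series(proj_vals, index=proj_years, name="projection"),
            )
        )
    return ClimateEnsemble(observed=observed, models=models)


@dataclass
class RecruitSimParams:
    """Settings for the synthetic log-recruitment-anomaly series.

    far_effect_shape 'linear': mean = effect_size * FAR.
    far_effect_shape 'threshold': mean drops by |effect_size| at
    FAR >= threshold, emulating a step response with greatly increased chance
    of recruitment failure beyond the threshold.
    """

    far_effect_shape: str = "threshold"
    threshold: float = 0.98
    effect_size: float = -2.0
    resid_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.far_effect_shape not in ("linear", "threshold"):
            raise ValueError("far_effect_shape must be 'linear' or 'threshold'")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if not self.resid_sd > 0:
            raise ValueError("resid_sd must be > 0")
        for name in ("threshold", "effect_size", "resid_sd"):
            _check_finite(name, getattr(self, name))


def recruitment_mean(far: np.ndarray, params: RecruitSimParams) -> np.ndarray:
    """Noise-free mean response of log recruitment to FAR."""
    far = np.asarray(far, dtype=float)
    if params.far_effect_shape == "linear":
        return params.effect_size * far
    return np.where(far >= params.threshold, params.effect_size, 0.0)


def simulate_recruitment(
    far_by_year: pd.Series | np.ndarray,
    params: RecruitSimParams,
    standardize: bool = False,
) -> pd.Series:
    """Annual log-recruitment anomalies driven by FAR.

    With ``standardize=True`` the output is rescaled to zero mean, unit
    variance (the convention for recruitment anomalies entering the
    FAR-response models).
    """
    far = np.asarray(far_by_year, dtype=float)
    if np.any((far < 0) | (far > 1)):
        raise ValueError("FAR values must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    vals = recruitment_mean(far, params) + rng.normal(0.0, params.resid_sd, far.size)
    if standardize:
        vals = (vals - vals.mean()) / vals.std(ddof=1)
    index = (
        far_by_year.index
        if isinstance(far_by_year, pd.Series)
        else pd.RangeIndex(far.size)
    )
    return pd.Series(vals, index=index, name="log_anomaly")


@dataclass
class SeineSimParams:
    """Settings for set-level zero-inflated negative binomial seine catches.

    The nearshore survey design emulated: 15 bays, ~6 sites per bay, each
    site visited a few times per year in mid-summer.  Covariate effects enter
    the count part with the stated sign and the zero part with the opposite
    sign (conditions raising mean catch lower the structural-zero odds), and
    bay/site intercepts enter both parts the same way.
    """

    n_years: int = 15
    n_bays: int = 15
    n_sites_per_bay: int = 6
    sets_per_site_year: int = 2
    zero_prob_intercept: float = -1.0
    mean_intercept: float = 3.0
    temp_effect: float = -1.5
    doy_effect: float = 0.2
    ssb_effect: float = 0.1
    bay_sd: float = 0.4
    site_sd: float = 0.3
    shape: float = 1.2
    seed: int = 0
    start_year: int = 2006
    zero_covariate_scale: float = 0.5

    def __post_init__(self):
        if not self.shape > 0:
            raise ValueError("shape must be > 0")
        if self.bay_sd < 0 or self.site_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        for name in ("zero_prob_intercept", "mean_intercept", "temp_effect",
                     "doy_effect", "ssb_effect", "bay_sd", "site_sd", "shape"):
            _check_finite(name, getattr(self, name))


def simulate_seine(
    params: SeineSimParams,
    far_by_year: np.ndarray | None = None,
) -> pd.DataFrame:
    """Set-level seine catches: year, day_of_year, bay, site, covariates, count.

    Temperature is a year-level anomaly; when ``far_by_year`` is given it is
    centered on 2*FAR - 1 so high-FAR years are warm, tying catch to FAR
    through the temperature effect.  SSB follows a slow random walk.
    day_of_year spans the July-August sampling window.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    years = params.start_year + np.arange(params.n_years)
    if far_by_year is not None:
        far = np.asarray(far_by_year, dtype=float)
        if far.size != params.n_years:
            raise ValueError("far_by_year length must equal n_years")
        if np.any((far < 0) | (far > 1)):
            raise ValueError("FAR values must lie in [0, 1]")
        temp_year = 2.0 * far - 1.0 + rng.normal(0, 0.25, params.n_years)
    else:
        temp_year = rng.normal(0.0, 1.0, params.n_years)
    ssb_year = np.cumsum(rng.normal(0.0, 0.3, params.n_years))
    ssb_year -= ssb_year.mean()

    bay_eff = rng.normal(0.0, params.bay_sd, params.n_bays)
    site_eff = rng.normal(
        0.0, params.site_sd, (params.n_bays, params.n_sites_per_bay)
    )

    rows = []
    for yi, year in enumerate(years):
        for b in range(params.n_bays):
            for s in range(params.n_sites_per_bay):
                n_sets = params.sets_per_site_year
                doy = rng.integers(182, 244, size=n_sets)  # July-August
                doy_c = (doy - 212.0) / 30.0
                re = bay_eff[b] + site_eff[b, s]
                eta_count = (
                    params.mean_intercept
                    + params.temp_effect * temp_year[yi]
                    + params.doy_effect * doy_c
                    + params.ssb_effect * ssb_year[yi]
                    + re
                )
                eta_zero = params.zero_prob_intercept - params.zero_covariate_scale * (
                    params.temp_effect * temp_year[yi]
                    + params.doy_effect * doy_c
                    + params.ssb_effect * ssb_year[yi]
                    + re
                )
                pi = 1.0 / (1.0 + np.exp(-eta_zero))
                mu = np.exp(eta_count)
                is_zero = rng.uniform(size=n_sets) < pi
                # NB(mu, shape) as gamma-Poisson mixture
                lam = rng.gamma(params.shape, mu / params.shape, size=n_sets)
                counts = np.where(is_zero, 0, rng.poisson(lam))
                for k in range(n_sets):
                    rows.append(
                        {
                            "year": int(year),
                            "day_of_year": int(doy[k]),
                            "bay": f"bay_{b + 1:02d}",
                            "site": f"bay_{b + 1:02d}_site_{s + 1:02d}",
                            "temperature": float(temp_year[yi]),
                            "ssb": float(ssb_year[yi]),
                            "count": int(counts[k]),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_survey_panel(
    trend: np.ndarray,
    loadings: np.ndarray,
    obs_sd: np.ndarray,
    missing_frac: np.ndarray,
    seed: int = 0,
    start_year: int = 1981,
) -> pd.DataFrame:
    """Multivariate annual survey panel sharing one latent trend.

    Each series i is ``loadings[i] * trend + N(0, obs_sd[i]^2)`` on the log
    scale, with entries removed completely at random at rate
    ``missing_frac[i]``.  Returns a wide DataFrame (year index, one column
    per series) with NaN marking missing surveys.
    """
    trend = np.asarray(trend, dtype=float)
    loadings = np.atleast_1d(np.asarray(loadings, dtype=float))
    obs_sd = np.atleast_1d(np.asarray(obs_sd, dtype=float))
    missing_frac = np.atleast_1d(np.asarray(missing_frac, dtype=float))
    if not (loadings.size == obs_sd.size == missing_frac.size):
        raise ValueError("loadings, obs_sd and missing_frac must have equal length")
    if np.any(obs_sd < 0):
        raise ValueError("obs_sd must be >= 0")
    if np.any((missing_frac < 0) | (missing_frac >= 1)):
        raise ValueError("missing_frac must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, m = trend.size, loadings.size
    data = loadings[None, :] * trend[:, None] + rng.normal(0, 1, (n, m)) * obs_sd
    for j in range(m):
        mask = rng.uniform(size=n) < missing_frac[j]
        data[mask, j] = np.nan
    years = start_year + np.arange(n)
    return pd.DataFrame(
        data, index=pd.Index(years, name="year"),
        columns=[f"series_{j + 1}" for j in range(m)],
    )


def write_simulation(
    out_dir: str | Path,
    ensemble: ClimateEnsemble | None = None,
    seine: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    recruitment: pd.Series | None = None,
    params: dict | None = None,
) -> dict:
    """Write generated tables as CSV plus a JSON sidecar of parameters.

    Returns a manifest dict of written paths.
    """
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    if ensemble is not None:
        p = out_dir / "climate_ensemble.csv"
        fio.write_ensemble(ensemble, p)
        manifest["climate_ensemble"] = str(p)
    if seine is not None:
        p = out_dir / "seine_catch.csv"
        seine.to_csv(p, index=False)
        manifest["seine_catch"] = str(p)
    if panel is not None:
        p = out_dir / "survey_panel.csv"
        fio.write_panel(panel, p)
        manifest["survey_panel"] = str(p)
    if recruitment is not None:
        p = out_dir / "recruitment.csv"
        recruitment.rename_axis("year").reset_index().to_csv(p, index=False)
        manifest["recruitment"] = str(p)
    sidecar = out_dir / "simulation_params.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
             for k, v in (params or {}).items()},
            fh, indent=2,
        )
    manifest["params"] = str(sidecar)
    return manifest
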