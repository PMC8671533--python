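import logging

import numpy as np
import pandas as pd
import pytest

import farrec

logging.getLogger("farrec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_ensemble():
    """Trended 30-year ensemble, 3 pseudo-models (fast attribution tests)."""
    return farrec.simulate_climate(
        farrec.ClimateSimParams(
            n_years_obs=30, n_models=3, n_years_pi=40, n_years_proj=20, seed=7
        )
    )


@pytest.fixture(scope="session")
def null_ensemble():
    """No-forcing null: zero trends everywhere."""
    return farrec.simulate_climate(
        farrec.ClimateSimParams(
            n_years_obs=30, trend_obs=0.0, trend_proj=0.0, n_models=3,
            n_years_pi=40, n_years_proj=20, seed=11,
        )
    )


@pytest.fixture(scope="session")
def seine_small():
    """~200-set seine data with a known temperature effect."""
    return farrec.simulate_seine(
        farrec.SeineSimParams(
            n_years=5, n_bays=4, n_sites_per_bay=2, sets_per_site_year=5,
            temp_effect=-0.5, seed=21,
        )
    )


def finite_difference_grad(logp_grad, theta, h=1e-5):
    """Central finite differences of the log posterior."""
    num = np.empty_like(theta)
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        num[i] = (logp_grad(tp)[0] - logp_grad(tm)[0]) / (2 * h)
    return num
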