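#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the data constellation of the Gulf-of-Alaska recruitment study: a
trended observed SST anomaly series with five pseudo-model preindustrial and
RCP-style projection realizations; a multi-survey recruitment panel sharing
one latent trend; set-level beach-seine catches tied to FAR through
temperature; and an assessment-style recruitment series with a threshold
response to FAR near 0.98.

Writes CSV inputs under results/data/.
"""

import logging

import numpy as np

import farrec
from farrec import io as fio
from farrec.simulate import write_simulation

logging.basicConfig(level=logging.WARNING)

SEED = 1
OUT = "results/data"


def main() -> None:
    climate = farrec.ClimateSimParams(seed=SEED)
    ens = farrec.simulate_climate(climate)

    far_tab = farrec.build_far_table(ens, "hindcast")
    far_year = far_tab.groupby("year")["far"].mean()

    recruit_params = farrec.RecruitSimParams(
        far_effect_shape="threshold", effect_size=-2.0, resid_sd=0.5,
        seed=SEED + 1,
    )
    # assessment-style series over 1977-2020, on the raw log scale
    far_hist = far_year.loc[1977:2020]
    recruit = farrec.simulate_recruitment(far_hist, recruit_params) + 3.5

    seine_params = farrec.SeineSimParams(
        n_years=15, start_year=2006, temp_effect=-0.5, seed=SEED + 2
    )
    seine = farrec.simulate_seine(
        seine_params, far_by_year=far_year.loc[2006:2020].to_numpy()
    )

    rng = np.random.default_rng(SEED + 3)
    trend = np.cumsum(rng.normal(0, 1, 40))
    panel = farrec.simulate_survey_panel(
        trend, [0.8, 0.6, 0.4, 0.0], [0.3, 0.4, 0.5, 0.5],
        [0.15, 0.2, 0.45, 0.1], seed=SEED + 4, start_year=1981,
    )

    manifest = write_simulation(
        OUT, ensemble=ens, seine=seine, panel=panel, recruitment=recruit,
        params={"climate": climate, "recruitment": recruit_params,
                "seine": seine_params, "seed": SEED},
    )
    print("wrote synthetic inputs:")
    for k, v in manifest.items():
        print(f"  {k}: {v}")
    print(f"observed years {ens.observed.index.min()}-{ens.observed.index.max()}; "
          f"{len(ens.models)} pseudo-models; {len(seine)} seine sets; "
          f"panel {panel.shape[0]} years x {panel.shape[1]} series")


if __name__ == "__main__":
    main()
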