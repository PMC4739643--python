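"""Shared hot-spot builders for calibration/power checks."""

import numpy as np

from energyscape.hotspots import Hotspot
from energyscape.landscape import CONTINUOUS_COVARIATES


def make_profile_hotspots(rng, n_ind=4, per_type=3, separated=False):
    """Hot spots with random (or type-separated) environmental profiles."""
    hs = []
    for i in range(n_ind):
        for typ in ("valley", "peak"):
            for _ in range(per_type):
                ncells = int(rng.integers(2, 12))
                if separated:
                    prof = {
                        "dist_forest_edge": rng.normal(
                            2.0 if typ == "valley" else -2.0, 1.0
                        ),
                        "prop_urban_240": rng.normal(
                            0.2 if typ == "valley" else 0.8, 0.15
                        ),
                        "heterogeneity": rng.normal(),
                        "dist_roads": rng.normal(),
                    }
                else:
                    prof = {c: rng.normal() for c in CONTINUOUS_COVARIATES}
                hs.append(
                    Hotspot(
                        type=typ,
                        cells=(np.zeros(ncells, int), np.arange(ncells)),
                        area=ncells * 900.0,
                        time_share=rng.uniform(0.001, 0.01),
                        env_profile=prof,
                        individual_id=f"I{i}",
                    )
                )
    return hs
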