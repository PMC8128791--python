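"""Published reference values from the spiral breast-CT phantom study
that this package models (nu:view system, 3D-printed breast shells with
agar/oil fillings).

These constants are inputs for validation round-trips — recipe
reproduction, dose-factor/recommendation consistency, MOSFET surface-dose
comparison — never outputs of the simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: printed emulsion component volumes (ml per 1-l batch) by glandular fraction
MIXTURE_VOLUMES_ML = {
    0.125: dict(agar=119, oil=831, lecithin=50),
    0.375: dict(agar=356, oil=594, lecithin=50),
    0.625: dict(agar=594, oil=356, lecithin=50),
    0.875: dict(agar=831, oil=119, lecithin=50),
}

#: published dose-factor lookup F (mGy/mA), rows = glandularity (fraction;
#: the printed 37.8% row label is a typo for 37.5%), columns = volume (cm^3)
DOSE_FACTOR_VOLUMES_CM3 = (248.0, 358.0, 1067.0)
DOSE_FACTOR_GLANDULARITIES = (0.125, 0.375, 0.625, 0.875)
DOSE_FACTOR_MGY_PER_MA = pd.DataFrame(
    [[0.25, 0.24, 0.19],
     [0.27, 0.25, 0.20],
     [0.28, 0.26, 0.20],
     [0.29, 0.27, 0.21]],
    index=pd.Index(DOSE_FACTOR_GLANDULARITIES, name="glandularity"),
    columns=pd.Index(DOSE_FACTOR_VOLUMES_CM3, name="volume_cm3"),
)

#: MOSFET surface-dose validation: measured vs simulated (mGy +- sd) and the
#: printed percent differences (computed by the study from unrounded doses)
MOSFET_VALIDATION = pd.DataFrame(
    [
        dict(phantom="large", measured_mgy=10.0, measured_sd=0.77,
             simulated_mgy=8.6, simulated_sd=1.01, printed_percent_diff=-13.7),
        dict(phantom="medium", measured_mgy=6.8, measured_sd=0.35,
             simulated_mgy=8.0, simulated_sd=0.80, printed_percent_diff=18.1),
        dict(phantom="small", measured_mgy=7.2, measured_sd=0.50,
             simulated_mgy=6.7, simulated_sd=0.37, printed_percent_diff=-7.7),
    ]
)

#: stated agreement bound for the MOSFET validation (percent)
MOSFET_PERCENT_DIFF_BOUND = 23.0

#: published recommendation table: optimal tube current (mA) and the dose it
#: implies (mGy), per phantom and glandularity.  The published mixture
#: columns 1..4 map to glandularity 87.5/62.5/37.5/12.5% (highest first) —
#: the mapping under which dose/current quotients reproduce the factor
#: lookup.  ``flagged`` marks entries whose dose exceeds the 6.5-mGy base
#: limit (the printed asterisks).
RECOMMENDATIONS = pd.DataFrame(
    [
        dict(phantom="large", glandularity=0.875, current_ma=25.0,
             dose_mgy=5.22, flagged=False),
        dict(phantom="large", glandularity=0.625, current_ma=32.0,
             dose_mgy=6.48, flagged=False),
        dict(phantom="large", glandularity=0.375, current_ma=32.0,
             dose_mgy=6.25, flagged=False),
        dict(phantom="large", glandularity=0.125, current_ma=32.0,
             dose_mgy=6.00, flagged=False),
        dict(phantom="medium", glandularity=0.875, current_ma=25.0,
             dose_mgy=6.81, flagged=True),
        dict(phantom="medium", glandularity=0.625, current_ma=25.0,
             dose_mgy=6.56, flagged=True),
        dict(phantom="medium", glandularity=0.375, current_ma=25.0,
             dose_mgy=6.29, flagged=False),
        dict(phantom="medium", glandularity=0.125, current_ma=25.0,
             dose_mgy=5.99, flagged=False),
        dict(phantom="small", glandularity=0.875, current_ma=25.0,
             dose_mgy=7.28, flagged=True),
        dict(phantom="small", glandularity=0.625, current_ma=25.0,
             dose_mgy=6.94, flagged=True),
        dict(phantom="small", glandularity=0.375, current_ma=25.0,
             dose_mgy=6.58, flagged=True),
        dict(phantom="small", glandularity=0.125, current_ma=25.0,
             dose_mgy=6.21, flagged=False),
    ]
)
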