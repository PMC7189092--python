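"""Reference values from the breast-cancer cohort analysis this package
emulates (522 patients, Mahdieh Oncology Center registry).

The registry data themselves are unpublished; what survives in print are the
cohort summaries (marginal survival milestones, category frequencies), the
censored-quantile-regression coefficient table over eleven quantile levels,
and a grid of predicted survival quartiles for eighteen covariate scenarios.
These constants are the reproduction surface for the scenario engine and the
calibration targets for the synthetic-cohort generator.
"""

from __future__ import annotations

import numpy as np

from .cohort import StandardizationParams

#: age standardization used throughout (cohort mean and SD, years)
AGE_STANDARDIZATION = StandardizationParams(mean_age=47.04, sd_age=10.70)

#: published quantile-process coefficients: level -> (intercept, z-age^2,
#: z-age, tumor size, involved lymph nodes), months per unit covariate
PUBLISHED_COEFFICIENTS: dict[float, tuple[float, ...]] = {
    0.01: (2.7, -1.2, 1.5, 0.5, -0.03),
    0.025: (9.2, -1.3, 0.2, -0.8, -0.1),
    0.05: (14.1, -1.2, -1.1, -1.3, -0.3),
    0.10: (25.1, -1.6, -4.0, -2.5, -0.4),
    0.25: (45.7, -0.5, -5.2, -3.2, -0.4),
    0.50: (66.8, -1.5, -5.0, -1.3, -0.8),
    0.75: (88.7, -3.9, -2.2, -1.2, -0.6),
    0.90: (92.7, -0.8, -3.1, 0.4, 0.2),
    0.95: (99.4, -1.0, -2.3, -0.4, 0.2),
    0.975: (102.6, -1.4, -1.8, -0.9, 0.1),
    0.99: (107.2, -1.8, -1.3, -1.42, -0.2),
}

#: published bootstrap standard errors (same layout, intercept SE not printed)
PUBLISHED_COEFFICIENT_SES: dict[float, tuple[float, ...]] = {
    0.01: (np.nan, 0.75, 1.67, 1.03, 0.3),
    0.025: (np.nan, 0.94, 1.89, 1.02, 0.27),
    0.05: (np.nan, 1.06, 2.33, 0.42, 0.15),
    0.10: (np.nan, 0.75, 2.34, 1.09, 0.59),
    0.25: (np.nan, 2.62, 2.69, 1.40, 0.53),
    0.50: (np.nan, 0.72, 3.30, 0.72, 0.48),
    0.75: (np.nan, 1.76, 3.81, 3.83, 0.27),
    0.90: (np.nan, 2.65, 1.48, 2.28, 0.61),
    0.95: (np.nan, 1.72, 3.40, 0.28, 0.47),
    0.975: (np.nan, 1.52, 2.41, 1.84, 0.50),
    0.99: (np.nan, 1.58, 3.02, 1.5, 0.52),
}

#: scenario grid axes (ages follow the printed grid headers)
SCENARIO_AGES = (40.0, 45.0, 55.0)
SCENARIO_NODES = (3, 6)
SCENARIO_SIZES = (1.5, 3.5, 6.0)
SCENARIO_TAUS = (0.25, 0.50, 0.75)

#: published predicted quartiles (months) keyed by
#: (tau, tumor_size, n_nodes, age)
PUBLISHED_SCENARIO_QUANTILES: dict[tuple[float, float, int, float], float] = {}
_Q25 = [42.91, 40.25, 36.22, 41.80, 39.14, 35.11,
        36.49, 33.82, 29.78, 35.36, 32.70, 28.72,
        28.42, 25.76, 21.73, 27.31, 24.65, 20.62]
_Q50 = [65.09, 62.90, 58.71, 62.73, 60.59, 56.36,
        62.40, 60.28, 56.04, 60.09, 57.94, 53.70,
        59.01, 56.95, 52.71, 56.76, 54.61, 50.73]
_Q75 = [85.16, 85.55, 82.35, 83.51, 83.92, 80.70,
        82.84, 83.23, 80.04, 81.19, 81.58, 78.39,
        79.94, 83.23, 80.04, 78.29, 81.58, 78.39]
for _tau, _vals in zip(SCENARIO_TAUS, (_Q25, _Q50, _Q75)):
    _i = 0
    for _size in SCENARIO_SIZES:
        for _nodes in SCENARIO_NODES:
            for _age in SCENARIO_AGES:
                PUBLISHED_SCENARIO_QUANTILES[(_tau, _size, _nodes, _age)] = _vals[_i]
                _i += 1

#: upper-quartile cells for the 6 cm column repeat the 3.5 cm values for two
#: of the three ages -- an apparent typesetting slip in the source table;
#: these cells are excluded from tolerance checks
SUSPECT_SCENARIO_CELLS = frozenset(
    (0.75, 6.0, nodes, age) for nodes in SCENARIO_NODES for age in SCENARIO_AGES
)

#: cohort-level summaries used as generator calibration targets
COHORT_N = 522
DEATH_PERCENT = 35.4
KM_MILESTONES = {12.0: 90.0, 36.0: 73.0, 60.0: 62.5}  # months -> percent surviving
TUMOR_BAND_PERCENTS = {"<2 cm": 62.1, "2-5 cm": 24.9, ">5 cm": 13.0}
NODE_BAND_PERCENTS = {"<=2": 52.2, "3-6": 27.1, ">=7": 20.7}
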