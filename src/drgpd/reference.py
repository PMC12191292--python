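"""Published reference summary statistics for the Fabry DRG imaging cohort.

The patient-level data behind the published DRG-PD study are not public;
what is public are the printed summary tables.  This module ships those
numbers as machine-readable inputs for worked examples and arithmetic
closure checks: the stratified group comparisons of the three DRG metrics
(medians, IQRs, Mann-Whitney p, Cliff's delta), the multivariable logistic
model for SFN status (coefficients, standard errors, z, p, and the fit
statistics), and the headline cohort marginals.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "group_effects",
    "logistic_table",
    "LOGISTIC_FIT_STATS",
    "COHORT_MARGINALS",
    "ROC_AUC_BY_PHENOTYPE",
]

#: Published logistic-model fit statistics (n = 80).
LOGISTIC_FIT_STATS = {
    "aic": 100.68,
    "residual_deviance": 80.68,
    "mcfadden_r2": 0.19,
    "lr_p": 0.028,
    "n": 80,
    "n_coefficients": 10,  # intercept + 9 covariates
}

#: Headline cohort marginals used by the synthetic generator defaults.
COHORT_MARGINALS = {
    "n": 80,
    "n_male": 38,
    "n_female": 42,
    "n_sfn": 25,
    "n_classical": 18,
    "n_late_onset_benign": 54,
    "n_vus": 8,
}

#: Published ROC AUC of DRG-PD for SFN, per phenotype subgroup.
ROC_AUC_BY_PHENOTYPE = {"classical": 0.96, "benign": 0.57}

_LOGISTIC_ROWS = [
    # term, estimate, std_error, z, p
    ("(Intercept)", -10.640, 3.986, -2.669, 0.008),
    ("age", -0.004, 0.022, -0.182, 0.855),
    ("sex_male", 1.108, 0.913, 1.214, 0.225),
    ("lyso_gb3", 0.009, 0.007, 1.195, 0.232),
    ("alpha_gal", 1.907, 2.898, 0.658, 0.511),
    ("drg_pd", 11.510, 4.914, 2.343, 0.019),
    ("drg_t2", 0.012, 0.020, 0.631, 0.528),
    ("drg_vol", -0.0012, 0.0007, -1.646, 0.100),
    ("phenotype_classical", -0.902, 0.791, -1.141, 0.254),
    ("prior_fd_therapy", 2.008, 0.762, 2.635, 0.008),
]

_GROUP_ROWS = [
    # stratum, metric, n_pos, median_pos, q1_pos, q3_pos, n_neg, median_neg, q1_neg, q3_neg, p, delta
    ("all", "drg_vol", 25, 1105.2, 784.4, 1390.9, 55, 1089.1, 884.3, 1377.1, 0.934, 0.01),
    ("all", "drg_t2", 25, 96.4, 89.9, 107.1, 55, 94.9, 85.1, 102.3, 0.461, 0.10),
    ("all", "drg_pd", 25, 0.710, 0.655, 0.765, 55, 0.667, 0.636, 0.725, 0.063, 0.26),
    ("m", "drg_vol", 15, 1302.0, 914.2, 1646.1, 23, 1354.5, 1080.4, 1561.5, 0.595, 0.11),
    ("m", "drg_t2", 15, 99.3, 90.0, 107.9, 23, 92.5, 82.8, 105.6, 0.378, 0.17),
    ("m", "drg_pd", 15, 0.681, 0.637, 0.766, 23, 0.656, 0.605, 0.700, 0.114, 0.31),
    ("f", "drg_vol", 10, 921.5, 606.5, 1117.2, 32, 992.2, 794.2, 1208.0, 0.631, 0.11),
    ("f", "drg_t2", 10, 94.3, 87.3, 102.6, 32, 95.6, 86.0, 101.8, 0.965, 0.01),
    ("f", "drg_pd", 10, 0.722, 0.668, 0.764, 32, 0.672, 0.649, 0.732, 0.202, 0.28),
    ("classical", "drg_vol", 7, 1003.1, 809.9, 1113.2, 11, 1181.0, 896.7, 1563.0, 0.319, 0.30),
    ("classical", "drg_t2", 7, 104.4, 93.5, 113.9, 11, 102.1, 92.0, 117.9, 1.0, 0.01),
    ("classical", "drg_pd", 7, 0.765, 0.761, 0.784, 11, 0.701, 0.687, 0.720, 0.0004, 0.92),
    ("classical;m", "drg_vol", 4, 809.9, 760.7, 1043.6, 6, 1314.4, 944.8, 1639.2, 0.352, 0.42),
    ("classical;m", "drg_t2", 4, 98.8, 89.8, 110.8, 6, 102.3, 91.8, 120.9, 0.610, 0.25),
    ("classical;m", "drg_pd", 4, 0.772, 0.750, 0.803, 6, 0.698, 0.635, 0.701, 0.019, 0.92),
    ("classical;f", "drg_vol", 3, 1105.2, 1054.1, 1113.2, 5, 1181.0, 896.7, 1262.6, 0.786, 0.20),
    ("classical;f", "drg_t2", 3, 104.4, 100.4, 112.6, 5, 102.1, 96.3, 102.7, 0.571, 0.33),
    ("classical;f", "drg_pd", 3, 0.765, 0.763, 0.774, 5, 0.713, 0.702, 0.726, 0.036, 1.00),
    ("benign", "drg_vol", 16, 1156.2, 750.1, 1449.3, 38, 1037.4, 852.2, 1348.3, 0.673, 0.08),
    ("benign", "drg_t2", 16, 92.3, 89.7, 99.8, 38, 94.1, 83.8, 101.4, 0.842, 0.04),
    ("benign", "drg_pd", 16, 0.674, 0.641, 0.736, 38, 0.664, 0.619, 0.719, 0.414, 0.15),
    ("benign;m", "drg_vol", 9, 1390.9, 1074.5, 1697.1, 15, 1329.7, 1122.7, 1525.1, 0.861, 0.05),
    ("benign;m", "drg_t2", 9, 99.3, 90.1, 100.4, 15, 91.8, 79.5, 100.8, 0.245, 0.30),
    ("benign;m", "drg_pd", 9, 0.668, 0.632, 0.744, 15, 0.656, 0.594, 0.689, 0.446, 0.20),
    ("benign;f", "drg_vol", 7, 768.4, 551.9, 1038.8, 23, 962.3, 580.3, 1044.7, 0.737, 0.09),
    ("benign;f", "drg_t2", 7, 89.9, 81.6, 94.7, 23, 94.4, 88.7, 101.3, 0.327, 0.26),
    ("benign;f", "drg_pd", 7, 0.694, 0.657, 0.722, 23, 0.664, 0.644, 0.725, 0.598, 0.14),
]


def logistic_table() -> pd.DataFrame:
    """Published multivariable logistic model for SFN status (n = 80)."""
    return pd.DataFrame(
        _LOGISTIC_ROWS, columns=["term", "estimate", "std_error", "z_value", "p_value"]
    )


def group_effects() -> pd.DataFrame:
    """Published stratified SFN-positive vs SFN-negative comparisons of the
    three DRG metrics (medians/IQRs in a.u., ms, mm^3; |Cliff's delta|)."""
    return pd.DataFrame(
        _GROUP_ROWS,
        columns=[
            "stratum",
            "metric",
            "n_pos",
            "median_pos",
            "q1_pos",
            "q3_pos",
            "n_neg",
            "median_neg",
            "q1_neg",
            "q3_neg",
            "p_value",
            "delta_abs",
        ],
    )
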