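"""Published summary statistics of the seven-subject [11C]PBR28 / XBD173
blocking study in high-affinity binders that this package models.

These printed group-level values serve two purposes: they set the scale of
the synthetic-data generator's defaults (regional baseline V_T, dispersion,
occupancy range), and they are the inputs to the summary-statistics
reproductions in :mod:`petblock.report` (regional percent-V_T-change table,
SIME-versus-Lassen comparison). Subject-level raw scans are not public; no
value here is ever used as a fitting target.
"""

from __future__ import annotations

import pandas as pd

#: Regional V_T (mL/cm3, mean and SD over 7 subjects) at baseline and after
#: XBD173 blocking, for the standard 2TCM and the vascular 2TCM1K variant,
#: with the printed percent V_T change (relative difference of the means,
#: printed as integer percent).
REGIONAL_VT_ROWS = [
    # region, 2TCM (base mean, sd, block mean, sd, %change), 2TCM1K (same)
    ("whole_brain", 4.72, 1.18, 2.16, 1.05, 54, 2.31, 0.63, 0.70, 0.26, 70),
    ("white_matter", 4.30, 0.95, 1.97, 0.58, 54, 1.34, 0.38, 0.62, 0.10, 54),
    ("gray_matter", 4.95, 1.26, 2.45, 1.62, 50, 2.64, 0.71, 0.76, 0.34, 71),
    ("occipital_lobe", 4.76, 1.26, 2.91, 2.36, 39, 2.56, 0.73, 0.70, 0.31, 73),
    ("temporal_lobe", 4.82, 1.16, 2.06, 0.85, 57, 2.43, 0.75, 0.73, 0.29, 70),
    ("frontal_lobe", 4.81, 1.21, 2.43, 1.57, 49, 2.49, 0.65, 0.73, 0.30, 71),
    ("parietal_lobe", 4.64, 1.18, 2.91, 2.65, 37, 2.42, 0.67, 0.71, 0.31, 71),
    ("amygdala", 6.67, 2.09, 1.62, 0.53, 76, 2.49, 1.55, 1.14, 0.22, 54),
    ("hippocampus", 5.25, 1.23, 1.88, 0.51, 64, 2.59, 1.07, 1.04, 0.35, 60),
    ("thalamus", 5.70, 1.28, 1.79, 0.45, 69, 2.45, 0.78, 0.90, 0.29, 63),
    ("striatum", 4.83, 1.01, 1.86, 0.60, 61, 2.62, 1.03, 0.74, 0.18, 72),
    ("cerebellum", 4.87, 1.25, 2.27, 1.44, 53, 2.71, 0.65, 0.78, 0.34, 71),
]

_COLS = [
    "region",
    "vt_baseline_2tcm",
    "sd_baseline_2tcm",
    "vt_block_2tcm",
    "sd_block_2tcm",
    "pct_change_2tcm",
    "vt_baseline_2tcm1k",
    "sd_baseline_2tcm1k",
    "vt_block_2tcm1k",
    "sd_block_2tcm1k",
    "pct_change_2tcm1k",
]


def regional_vt_table() -> pd.DataFrame:
    """Printed regional V_T summary as a DataFrame."""
    return pd.DataFrame(REGIONAL_VT_ROWS, columns=_COLS)


#: Per-subject V_ND estimates (mL/cm3): SIME from the baseline scan, the
#: occupancy-plot (Lassen) estimate after blocking with 2TCM and 2TCM1K
#: kinetics, and the printed SIME-vs-Lassen relative difference (%).
SUBJECT_VND_ROWS = [
    ("#305", 1.24, 5.55, -78, 0.14),
    ("#314", 0.94, 3.05, -69, 0.78),
    ("#316", 1.68, 2.31, -27, 1.03),
    ("#337", 1.14, 1.51, -24, 0.27),
    ("#338", 1.17, 2.09, -44, 1.01),
    ("#339", 0.71, 1.67, -58, 0.89),
    ("#378", 1.24, 1.50, -17, 0.75),
]


def subject_vnd_table() -> pd.DataFrame:
    """Printed per-subject V_ND estimates as a DataFrame."""
    return pd.DataFrame(
        SUBJECT_VND_ROWS,
        columns=["subject", "sime_vnd", "lassen_vnd_2tcm", "rel_dif_pct", "lassen_vnd_2tcm1k"],
    )


#: Population-constrained occupancy-plot V_ND (mL/cm3) with 95% CI, 2TCM.
POPULATION_VND = 1.99
POPULATION_VND_CI = (1.90, 2.08)
#: Blocking-dose target occupancy range (fraction of TSPO sites).
TARGET_OCCUPANCY_RANGE = (0.66, 0.77)
#: The single high-uptake subject's baseline V_T excess over the group mean.
OUTLIER_VT_INFLATION = 0.38
#: Injected dose (MBq, mean and SD) at baseline and after blocking.
INJECTED_DOSE_BASELINE = (321.0, 32.0)
INJECTED_DOSE_BLOCKING = (302.0, 75.0)
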