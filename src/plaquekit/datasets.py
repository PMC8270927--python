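"""Small bundled reference datasets.

``pet_pilot_cohort`` transcribes the published per-patient 18F-FDG uptake
table of a 12-patient pilot cohort with high-grade carotid stenosis
(plaque SUV_max/SUV_mean, inferior-vena-cava blood-pool SUV_max/SUV_mean,
and the reported TBR).  It is the desk-scale input for reproducing the
cohort's TBR arithmetic and group summary.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["pet_pilot_cohort"]

_ROWS = [
    # patient, plaque_suv_max, plaque_suv_mean, tbr_reported, ivc_suv_max, ivc_suv_mean
    (1, 3.55, 2.13, 1.60, 2.8, 1.33),
    (2, 3.13, 1.99, 1.81, 2.5, 1.10),
    (3, 10.73, 4.54, 1.54, 6.2, 2.95),
    (4, 2.30, 1.65, 1.04, 3.7, 1.58),
    (5, 4.67, 2.32, 2.68, 3.5, 0.87),
    (6, 1.73, 1.09, 1.17, 1.8, 0.93),
    (7, 3.06, 2.08, 1.10, 3.2, 1.88),
    (8, 2.82, 1.93, 1.27, 2.5, 1.52),
    (9, 2.92, 1.88, 1.12, 3.7, 1.68),
    (10, 3.11, 1.86, 1.24, 3.0, 1.50),
    (11, 3.32, 1.85, 2.02, 3.7, 0.92),
    (12, 3.50, 1.96, 1.32, 4.5, 1.48),
]


def pet_pilot_cohort() -> pd.DataFrame:
    """Published per-patient plaque and blood-pool SUVs of the pilot cohort.

    Columns: ``plaque_suv_max``, ``plaque_suv_mean``, ``tbr_reported``,
    ``ivc_suv_max``, ``ivc_suv_mean`` (inferior vena cava = venous blood
    pool), indexed by patient number.  TBR = plaque SUV_mean / blood-pool
    SUV_mean.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "patient",
            "plaque_suv_max",
            "plaque_suv_mean",
            "tbr_reported",
            "ivc_suv_max",
            "ivc_suv_mean",
        ],
    ).set_index("patient")
    return df
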