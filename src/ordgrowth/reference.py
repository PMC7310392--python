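"""Reference values from the motivating cohort study.

The package models longitudinal WHO immunological stages in a cohort of
219 seroconverting South African women followed for up to 13.13 years.
This module collects the study's published summary numbers that serve as
inputs and defaults elsewhere: baseline category counts (used to verify
descriptive-table arithmetic), the exponentiated model thresholds, and the
random-components block of the fitted growth model.

The baseline BMI counts sum to 218, not 219 — one subject's BMI was
missing — which is why percentage denominators are per-variable
non-missing counts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

N_SUBJECTS = 219

#: variable -> list of (category label, count). Counts are the published
#: baseline table; None entries pad a variable to 219 with missing values.
BASELINE_COUNTS: dict[str, list[tuple[str, int]]] = {
    "education": [("<=Gr8", 16), ("Gr9-10", 50), (">=Gr11", 153)],
    "marital": [("single", 34), ("stable", 174), ("many", 11)],
    "contraceptive": [("no", 40), ("yes", 179)],
    "anemia": [("no", 208), ("yes", 11)],
    "tb": [("no", 201), ("yes", 18)],
    "immunological_state": [
        ("<200", 9),
        ("200-349", 41),
        ("350-499", 89),
        (">=500", 80),
    ],
    "age_group": [("18-20", 29), ("21-39", 178), (">=40", 12)],
    "bmi_group": [("underweight", 5), ("healthy", 76), ("overweight_obese", 137)],
    "sex_under_alcohol": [("no", 197), ("yes", 22)],
}

#: exponentiated thresholds exp(delta^(k)) of the fitted growth model
THRESHOLD_ORS = (0.02, 19.87, 24.51)

#: random components: intercept variance, intercept-slope covariance, slope variance
RANDOM_COMPONENTS = (12.21, -0.36, 0.02)


def make_baseline_table() -> pd.DataFrame:
    """Subject-level table (219 rows) realizing the published baseline counts.

    Category assignment within a variable is arbitrary (row order carries no
    information); variables whose counts sum below 219 are padded with
    missing values.
    """
    data = {}
    for var, pairs in BASELINE_COUNTS.items():
        col: list = []
        for level, count in pairs:
            col.extend([level] * count)
        col.extend([None] * (N_SUBJECTS - len(col)))
        data[var] = col
    return pd.DataFrame(data)


def baseline_category_spec() -> dict[str, list[str]]:
    """Declared category sets matching :data:`BASELINE_COUNTS`."""
    return {var: [lv for lv, _ in pairs] for var, pairs in BASELINE_COUNTS.items()}


def reference_re_cov() -> np.ndarray:
    v0, c, v1 = RANDOM_COMPONENTS
    return np.array([[v0, c], [c, v1]])
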