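"""Reference cohort tables.

Summary demographics of the hard-of-hearing (CHH, n = 17) and
normal-hearing (CNH, n = 23) reference cohort the simulator emulates:
group means, SDs and counts for the continuous measures, and the
categorical sex and handedness tables.  These are inputs to the
demographic-comparison operations (computed from summaries, not raw
scores, which are not public).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cohort_summary",
    "sex_table",
    "handedness_table",
    "CHH_BEPTA_MEAN",
    "CHH_BEPTA_SD",
    "CHH_BEPTA_RANGE",
    "CHH_HA_USE_MEAN",
    "CHH_HA_USE_SD",
    "CHH_HA_USE_RANGE",
    "BEPTA_HA_USE_CORR",
]

# CHH auditory-experience covariates (school-year averages)
CHH_BEPTA_MEAN, CHH_BEPTA_SD = 44.82, 15.40          # dB HL
CHH_BEPTA_RANGE = (24.0, 76.0)
CHH_HA_USE_MEAN, CHH_HA_USE_SD = 80.12, 29.17        # hours/week
CHH_HA_USE_RANGE = (0.0, 112.0)
BEPTA_HA_USE_CORR = 0.588

_CONTINUOUS = [
    # variable, cnh_mean, cnh_sd, cnh_n, chh_mean, chh_sd, chh_n
    ("age_years", 11.42, 2.47, 23, 12.14, 2.24, 17),
    ("wasi_vci", 109.04, 13.04, 23, 103.35, 9.54, 17),
    ("wasi_pri", 105.57, 12.83, 23, 107.94, 11.09, 17),
    ("wasi_fsiq4", 108.43, 11.04, 23, 106.47, 9.59, 17),
    ("dkefs_letter_fluency", 9.43, 3.53, 21, 9.73, 2.71, 16),
    ("dkefs_category_fluency", 11.00, 3.81, 21, 11.00, 3.30, 16),
    ("adhd_academic", 3.36, 0.83, 21, 3.65, 0.79, 16),
    ("adhd_classroom", 3.86, 1.02, 21, 3.70, 0.80, 16),
    ("maternal_education", 16.09, 2.16, 22, 15.59, 2.09, 17),
]


def cohort_summary() -> pd.DataFrame:
    """Continuous-variable summary statistics per group."""
    return pd.DataFrame(
        _CONTINUOUS,
        columns=["variable", "cnh_mean", "cnh_sd", "cnh_n",
                 "chh_mean", "chh_sd", "chh_n"]).set_index("variable")


def sex_table() -> pd.DataFrame:
    """Sex counts (rows: CNH, CHH; columns: M, F)."""
    return pd.DataFrame([[15, 8], [11, 6]], index=["CNH", "CHH"],
                        columns=["M", "F"])


def handedness_table(collapse: bool = True) -> pd.DataFrame:
    """Handedness counts; collapsed to right vs. non-right by default."""
    full = pd.DataFrame([[21, 2, 0], [13, 3, 1]], index=["CNH", "CHH"],
                        columns=["R", "L", "Am"])
    if not collapse:
        return full
    out = full[["R"]].copy()
    out["non-R"] = full["L"] + full["Am"]
    return out
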