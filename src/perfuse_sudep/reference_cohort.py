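"""Published summary tables of the nine-patient reference DRFE SPECT cohort.

The cohort behind this analysis — nine adults with drug-resistant focal
epilepsy, 29 paired interictal/ictal SPECT scans — is not publicly deposited;
what is public are the per-patient clinical features and the per-patient
extreme-cluster perfusion summaries.  They are transcribed here verbatim so
the descriptive statistics the analysis reports (SUDEP-7 score distribution,
injection-time spread, hypo/hyper cluster PI ranges) can be recomputed and
checked against the printed values, and so the synthetic cohort can be
parameterised to the same conditions.

Known internal inconsistencies of the published summaries (documented, not
"fixed"): the printed mean seizure duration (91.82 s) does not match either
table's durations (table mean 65.2 s); the printed interictal-hyper and
ictal-hypo summary ranges do not match their table columns.  All quantities
this package asserts are recomputed from the tables themselves.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "demographics",
    "cluster_table",
    "sudep7_scores",
    "injection_times",
    "seizure_durations",
    "onset_sides",
]

# Demographic / clinical features (one row per patient).
_DEMOGRAPHICS = [
    # patient, age, onset_age, duration_y, sex, epilepsy_type, onset_side, sz_duration_s, sudep7
    ("P1", 32, 8.0, 24, "female", "TLE", "left", 109, 3),
    ("P2", 33, 0.8, 32, "female", "TLE", "left", 62, 5),
    ("P3", 21, 6.0, 15, "male", "NLFE", "right", 95, 7),
    ("P4", 25, 9.0, 16, "female", "LFE", "right", 73, 7),
    ("P5", 15, 4.0, 11, "male", "NLFE", "right", 66, 7),
    ("P6", 15, 14.0, 1, "female", "NLFE", "right", 19, 4),
    ("P7", 18, 8.0, 10, "male", "NLFE", "left", 56, 7),
    ("P8", 17, 3.0, 14, "male", "LFE", "left", 35, 7),
    ("P9", 28, 3.0, 25, "male", "NLFE", "right", 72, 4),
]

# Per-patient extreme-cluster summaries: mean, sample SD, N structures and
# N subcortical for the hypo- and hyperperfused clusters in each state, plus
# ictal injection time and seizure duration.
_CLUSTERS = [
    # patient,
    # inter_hypo (mean, sd, n, n_subc), inter_hyper (...),
    # injection_time_s, seizure_duration_s,
    # ictal_hypo (...), ictal_hyper (...),
    # change_decrease (...), change_increase (...)
    ("P1", (0.51, 0.07, 2, 1), (1.21, 0.02, 9, 4), 7, 109,
     (0.41, 0.14, 3, 2), (1.46, 0.11, 5, 2), (-0.61, 0.09, 13, 11), (0.27, 0.11, 11, 6)),
    ("P2", (0.64, 0.02, 13, 10), (1.24, 0.04, 4, 0), 17, 62,
     (0.41, 0.14, 5, 3), (1.29, 0.07, 14, 9), (-0.13, 0.05, 19, 2), (0.68, 0.14, 7, 6)),
    ("P3", (0.45, 0.11, 7, 7), (1.21, 0.03, 13, 3), 2, 95,
     (0.46, 0.11, 7, 6), (1.37, 0.00, 16, 3), (-0.20, 0.07, 11, 3), (0.37, 0.12, 7, 2)),
    ("P4", (0.42, 0.10, 8, 8), (1.16, 0.00, 9, 1), 8, 66,
     (0.59, 0.15, 7, 6), (1.30, 0.06, 4, 3), (-0.12, 0.04, 9, 1), (0.73, 0.44, 10, 2)),
    ("P5", (0.57, 0.08, 7, 7), (1.21, 0.04, 6, 2), 4, 19,
     (0.45, 0.08, 4, 4), (1.16, 0.02, 9, 3), (-0.13, 0.03, 20, 7), (0.27, 0.07, 4, 2)),
    ("P6", (0.48, 0.02, 6, 4), (1.33, 0.04, 6, 3), 6, 56,
     (0.54, 0.10, 8, 8), (1.28, 0.10, 14, 3), (-0.47, 0.10, 2, 2), (0.32, 0.49, 4, 3)),
    ("P7", (0.60, 0.01, 3, 3), (1.24, 0.03, 10, 5), 10, 35,
     (0.50, 0.14, 7, 6), (1.16, 0.04, 12, 3), (-0.47, 0.10, 11, 6), (0.11, 0.03, 14, 3)),
    ("P8", (0.54, 0.11, 7, 7), (1.16, 0.04, 10, 1), 5, 72,
     (0.74, 0.03, 5, 4), (1.44, 0.09, 4, 4), (-0.11, 0.04, 24, 6), (1.08, 0.21, 6, 6)),
    ("P9", (0.62, 0.06, 4, 3), (1.77, 0.20, 3, 0), 3, 73,
     (0.57, 0.02, 4, 3), (1.44, 0.02, 11, 2), (-0.34, 0.11, 3, 2), (0.25, 0.09, 15, 3)),
]


def demographics() -> pd.DataFrame:
    """Clinical/demographic features, indexed by patient."""
    cols = ["age", "onset_age", "duration_y", "sex", "epilepsy_type",
            "onset_side", "seizure_duration_s", "sudep7_score"]
    df = pd.DataFrame([r[1:] for r in _DEMOGRAPHICS],
                      index=pd.Index([r[0] for r in _DEMOGRAPHICS], name="patient"),
                      columns=cols)
    return df


def cluster_table() -> pd.DataFrame:
    """Per-patient cluster summaries, one column block per state/role."""
    rows = []
    for rec in _CLUSTERS:
        patient = rec[0]
        blocks = {
            ("interictal", "hypo"): rec[1],
            ("interictal", "hyper"): rec[2],
            ("ictal", "hypo"): rec[5],
            ("ictal", "hyper"): rec[6],
            ("change", "decrease"): rec[7],
            ("change", "increase"): rec[8],
        }
        row = {"patient": patient, "injection_time_s": rec[3], "seizure_duration_s": rec[4]}
        for (state, role), (mean, sd, n, n_subc) in blocks.items():
            row[f"{state}_{role}_mean"] = mean
            row[f"{state}_{role}_sd"] = sd
            row[f"{state}_{role}_n"] = n
            row[f"{state}_{role}_n_subc"] = n_subc
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")


def sudep7_scores() -> pd.Series:
    return demographics()["sudep7_score"]


def injection_times() -> pd.Series:
    return cluster_table()["injection_time_s"]


def seizure_durations() -> pd.Series:
    return demographics()["seizure_duration_s"]


def onset_sides() -> pd.Series:
    return demographics()["onset_side"]
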