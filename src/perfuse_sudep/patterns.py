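"""Cross-patient pattern aggregation and descriptive summaries.

Per-patient extreme-cluster structure sets (hypoperfused / hyperperfused per
state, increase / decrease for the change pattern) are aggregated into a
structure-by-state match table: in how many of the n patients does each
structure fall in the extreme set, as a count and a percent.  Per-scan cluster
summaries (mean +/- SD of member perfusion indexes, N structures and N
subcortical) reproduce the layout of the cohort's published cluster table.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

__all__ = ["match_frequencies", "summarize_clusters", "describe"]

ROLES_BY_STATE = {
    "interictal": ("hypo", "hyper"),
    "ictal": ("hypo", "hyper"),
    "change": ("decrease", "increase"),
}


def _percent(count: int, n: int, style: str) -> float:
    raw = 100.0 * count / n
    if style == "round":
        return round(raw, 1)
    if style == "truncate":
        return math.floor(raw * 10.0) / 10.0
    raise ValueError(f"unknown percent style {style!r}")


def match_frequencies(
    extreme_sets: dict, n_patients: int, *, percent_style: str = "round"
) -> pd.DataFrame:
    """Per-structure match counts across patients.

    ``extreme_sets`` maps ``(state, role)`` -> ``{patient: set of structures}``.
    Returns a tidy frame (structure, state, role, count, n_patients, percent);
    percents to one decimal, rounded or truncated per ``percent_style`` (the
    published figures truncate: 8/9 prints as 88.8).
    """
    if n_patients < 1:
        raise ValueError("need >= 1 patient")
    rows = []
    for (state, role), by_patient in sorted(extreme_sets.items()):
        counts: dict[str, int] = {}
        for patient, members in by_patient.items():
            for s in members:
                counts[s] = counts.get(s, 0) + 1
        for s, c in sorted(counts.items()):
            rows.append(
                {
                    "structure": s,
                    "state": state,
                    "role": role,
                    "count": c,
                    "n_patients": n_patients,
                    "percent": _percent(c, n_patients, percent_style),
                }
            )
    return pd.DataFrame(rows, columns=["structure", "state", "role", "count", "n_patients", "percent"])


def describe(values) -> dict:
    """Mean, sample SD (n-1), SE, median, min, max of a 1-D sample."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("describe needs at least one value")
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {
        "n": int(n),
        "mean": float(np.mean(x)),
        "sd": sd,
        "se": sd / math.sqrt(n),
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def summarize_clusters(
    solutions: dict,
    pi_vectors: dict,
    atlas,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per patient/state/role cluster summary rows.

    ``solutions`` maps ``(patient, state)`` -> ClusterSolution; ``pi_vectors``
    maps the same keys to PerfusionVector.  For each scan the extreme clusters
    yield mean and sample SD of member values, N and N subcortical.  A single
    member reports SD 0 with ``single_member=True``; an empty role reports
    N = 0 with mean NaN and ``empty=True``.  Injection time and seizure
    duration columns are joined from ``clinical`` (indexed by patient) when
    present.
    """
    rows = []
    for (patient, state), sol in sorted(solutions.items()):
        vec = pi_vectors[(patient, state)]
        roles = ROLES_BY_STATE.get(state, ("hypo", "hyper"))
        for role, cluster in zip(roles, (sol.hypo_cluster, sol.hyper_cluster)):
            members = sol.members(cluster)
            vals = vec.values.reindex(members).to_numpy(dtype=float)
            n = len(members)
            row = {
                "patient": patient,
                "state": state,
                "role": role,
                "mean": float(np.mean(vals)) if n else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                "n": n,
                "n_subc": sum(1 for m in members if atlas.is_subcortical(m)),
                "single_member": n == 1,
                "empty": n == 0,
            }
            if clinical is not None and patient in clinical.index:
                for col in ("injection_time_s", "seizure_duration_s"):
                    if col in clinical.columns:
                        row[col] = clinical.loc[patient, col]
            rows.append(row)
    return pd.DataFrame(rows)
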