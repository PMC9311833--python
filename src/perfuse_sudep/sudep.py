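"""SUDEP-7 risk scoring and perfusion-change feature screening.

The SUDEP-7 inventory sums seven weighted clinical risk factors:

1. generalized tonic-clonic (GTC) seizures > 3 in the last year
2. GTC seizures > 0 in the last year (scored 0 when item 1 is present)
3. any seizure > 0 in the last year (scored 0 when item 4 is present)
4. any seizure > 50 per month in the last year
5. epilepsy duration >= 30 years
6. three or more antiepileptic drugs
7. intellectual disability

The published inventory is weighted with a 0-10 ceiling; the item weights are
not printed, so this package defaults to w = (2, 1, 1, 2, 2, 2, 2), the unique
simple assignment whose maximum under the two mutual-exclusion rules is
exactly 10 and which produces the odd scores seen in the reference cohort.
The weights are configuration, not a clinical claim.  Scores above 5 are the
high-risk stratum.

Feature screening ranks each structure's interictal->ictal perfusion change as
a predictor of the SUDEP-7 score: the structure's change values are binned
into equal-width intervals over their observed range, empty intervals are
dropped, and a one-way F statistic of the score across occupied bins (the
Fisher criterion of the screening procedure, treated as a regression problem)
ranks the structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Sudep7Record",
    "DEFAULT_WEIGHTS",
    "score_sudep7",
    "screen_features",
    "spearman",
]

DEFAULT_WEIGHTS = (2, 1, 1, 2, 2, 2, 2)
ITEM_COLUMNS = tuple(f"i{j}" for j in range(1, 8))
HIGH_RISK_THRESHOLD = 5  # stratum is high iff score > 5


class SudepError(ValueError):
    pass


@dataclass(frozen=True)
class Sudep7Record:
    """Scored SUDEP-7 inventory for one patient."""

    patient_id: str
    items: tuple[bool, bool, bool, bool, bool, bool, bool]
    score: int
    stratum: str  # "high" | "low"


def score_sudep7(items, weights=DEFAULT_WEIGHTS, *, patient_id: str = "?") -> Sudep7Record:
    """Score the seven inventory items under the mutual-exclusion rules.

    ``items`` is a sequence or mapping of seven booleans (i1..i7).  Item 2 is
    zeroed when item 1 is present; item 3 is zeroed when item 4 is present.
    """
    if isinstance(items, dict):
        vals = tuple(bool(items[c]) for c in ITEM_COLUMNS)
    else:
        vals = tuple(bool(v) for v in items)
    if len(vals) != 7:
        raise SudepError(f"need exactly 7 items, got {len(vals)}")
    w = tuple(int(x) for x in weights)
    if len(w) != 7 or any(x < 0 for x in w):
        raise SudepError("weights must be 7 non-negative integers")
    ceiling = w[0] + w[3] + w[4] + w[5] + w[6]  # max under exclusion rules
    if ceiling > 10:
        raise SudepError(f"weights exceed the inventory's 0-10 ceiling (max {ceiling})")
    effective = list(vals)
    if vals[0]:
        effective[1] = False  # GTC>0 scores 0 when GTC>3 present
    if vals[3]:
        effective[2] = False  # any seizure>0 scores 0 when >50/month present
    score = sum(wi for wi, vi in zip(w, effective) if vi)
    stratum = "high" if score > HIGH_RISK_THRESHOLD else "low"
    return Sudep7Record(patient_id=patient_id, items=vals, score=score, stratum=stratum)


def score_clinical_table(clinical: pd.DataFrame, weights=DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Score every row of a clinical table with i1..i7 boolean columns."""
    records = []
    for patient, row in clinical.iterrows():
        rec = score_sudep7({c: row[c] for c in ITEM_COLUMNS}, weights, patient_id=str(patient))
        records.append({"patient": rec.patient_id, "score": rec.score, "stratum": rec.stratum})
    return pd.DataFrame(records).set_index("patient")


def _merge_sparse_bins(bin_ids: list, members: dict, centers: dict, min_size: int = 2):
    """Merge bins with < min_size members into the nearest occupied neighbour.

    At desk-scale n a 10-interval grid leaves many singleton bins; singletons
    contribute no within-group degrees of freedom, which lets the F statistic
    blow up to infinity on pure overfit.  Requiring >= 2 members per group
    keeps the within-group mean square meaningful.
    """
    bin_ids = sorted(bin_ids)
    while len(bin_ids) > 1:
        sizes = {b: len(members[b]) for b in bin_ids}
        small = [b for b in bin_ids if sizes[b] < min_size]
        if not small:
            break
        b = small[0]
        neighbours = [nb for nb in bin_ids if nb != b]
        target = min(neighbours, key=lambda nb: (abs(centers[nb] - centers[b]), nb))
        members[target] = members[target] + members[b]
        centers[target] = float(np.mean([centers[target], centers[b]]))
        bin_ids.remove(b)
        del members[b], centers[b]
    return bin_ids, members


def _binned_f(x: np.ndarray, y: np.ndarray, n_intervals: int):
    """One-way F of y across equal-width bins of x; None when degenerate."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return None  # constant predictor: zero range
    edges = np.linspace(lo, hi, n_intervals + 1)
    bins = np.clip(np.digitize(x, edges[1:-1]), 0, n_intervals - 1)
    occupied = [b for b in range(n_intervals) if np.any(bins == b)]
    # runs of occupied intervals: an empty interval marks a real gap in the
    # predictor, adjacency does not — adjacent occupied intervals are one group
    runs: list[list[int]] = [[occupied[0]]]
    for b in occupied[1:]:
        if b == runs[-1][-1] + 1:
            runs[-1].append(b)
        else:
            runs.append([b])
    run_ids = list(range(len(runs)))
    members = {r: [i for b in runs[r] for i in np.flatnonzero(bins == b)] for r in run_ids}
    centers = {r: float(np.mean(x[members[r]])) for r in run_ids}
    run_ids, members = _merge_sparse_bins(run_ids, members, centers)
    occupied = run_ids
    groups = [y[np.asarray(members[b])] for b in occupied]
    k = len(groups)
    n = len(y)
    if k < 2 or n - k < 1:
        return None  # too few occupied bins / no within degrees of freedom
    grand = float(np.mean(y))
    ss_between = sum(len(g) * (float(np.mean(g)) - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        if ss_between <= 0:
            return 0.0, df_b, df_w, 1.0
        return float("inf"), df_b, df_w, 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return F, df_b, df_w, p


def screen_features(
    X: pd.DataFrame,
    y: pd.Series,
    n_intervals: int = 10,
    *,
    top_k: int = 3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Binned-predictor F screening of per-structure change values against scores.

    ``X`` is patients x structures (interictal->ictal change values), ``y`` the
    per-patient SUDEP-7 scores.  Each structure is binned over its own observed
    range into ``n_intervals`` equal-width intervals; empty intervals are
    dropped and bins with fewer than two patients are merged into their nearest
    occupied neighbour (see ``_merge_sparse_bins``); the one-way F of ``y``
    across the resulting bins ranks the structures (descending F).  Degenerate
    structures (constant change, or no residual degrees of freedom) get
    ``flag=True`` and rank last.  A structure
    is ``selected`` when it sits in the top ``top_k`` by F or has p below
    ``p_threshold``.
    """
    if n_intervals < 2:
        raise SudepError("n_intervals must be >= 2")
    y_arr = y.reindex(X.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(y_arr)):
        raise SudepError("scores missing for some patients in X")
    rows = []
    for structure in X.columns:
        x = X[structure].to_numpy(dtype=float)
        res = _binned_f(x, y_arr, n_intervals)
        if res is None:
            rows.append(
                {"structure": structure, "F": float("nan"), "df_between": 0,
                 "df_within": 0, "p": float("nan"), "flag": True}
            )
        else:
            F, df_b, df_w, p = res
            rows.append(
                {"structure": structure, "F": F, "df_between": df_b,
                 "df_within": df_w, "p": p, "flag": False}
            )
    out = pd.DataFrame(rows).set_index("structure")
    # rank by F descending; degenerate (flagged) structures last, stable order
    sort_key = out["F"].fillna(-np.inf)
    order = sort_key.sort_values(ascending=False, kind="stable").index
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    out["selected"] = (~out["flag"]) & (
        (out["rank"] <= top_k) | (out["p"] < p_threshold)
    )
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties); errors on constant input."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise SudepError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SudepError("spearman is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def hypo_burden_correlation(
    summary: pd.DataFrame, scores: pd.Series, *, state: str = "ictal"
) -> dict:
    """Spearman correlation of extreme-hypo-cluster size with SUDEP-7 score.

    Uses the per-patient hypoperfused-cluster rows of a cluster summary for
    ``state`` and computes both the total-N and the subcortical-N variant.
    Degenerate (constant) counts yield None for that variant.
    """
    rows = summary[(summary["state"] == state) & (summary["role"] == "hypo")]
    rows = rows.set_index("patient")
    out = {}
    for label, col in (("n_total", "n"), ("n_subcortical", "n_subc")):
        counts = rows[col].reindex(scores.index).astype(float)
        try:
            out[label] = spearman(counts.to_numpy(), scores.to_numpy(dtype=float))
        except SudepError:
            out[label] = None
    return out
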