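"""Univariate k-means, the exact DP oracle, and v-fold K selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from perfuse_sudep.cluster import (
    ClusterError,
    cluster_scan,
    dp_kmeans_1d,
    kmeans_1d,
    label_extremes,
    select_k_vfold,
)


def _series(values):
    return pd.Series({f"s{i}": v for i, v in enumerate(values)})


def exhaustive_optimal_inertia(values, k):
    """Independent oracle: best inertia over ALL set partitions into k groups.

    Feasible only for tiny n; makes no contiguity assumption, so it checks the
    DP's structure as well as its arithmetic.
    """
    values = list(values)
    n = len(values)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        cost = 0.0
        for c in range(k):
            member = [v for v, l in zip(values, labels) if l == c]
            cost += float(np.sum((np.asarray(member) - np.mean(member)) ** 2))
        best = min(best, cost)
    return best


def test_k1_closed_form():
    v = _series([1.0, 2.0, 4.0])
    sol = kmeans_1d(v, 1, seed=0)
    assert sol.centroids[0] == pytest.approx(v.mean())
    assert sol.inertia == pytest.approx(float(((v - v.mean()) ** 2).sum()))


def test_three_well_separated_pairs():
    v = _series([0.5, 0.52, 1.0, 1.02, 1.5, 1.52])
    for engine in ("lloyd", "dp"):
        sol = cluster_scan(v, 3, engine=engine, seed=1)
        assert np.allclose(sol.centroids, [0.51, 1.01, 1.51])
        assert sol.assignment.tolist() == [0, 0, 1, 1, 2, 2]
        assert sol.inertia == pytest.approx(sol.recompute_inertia(v))


@pytest.mark.parametrize("k", [2, 3])
def test_dp_matches_exhaustive_partition_oracle(k):
    rng = np.random.default_rng(11)
    for _ in range(10):
        v = _series(rng.uniform(0, 1, size=8).round(3))
        dp = dp_kmeans_1d(v, k)
        assert dp.inertia == pytest.approx(exhaustive_optimal_inertia(v, k), abs=1e-12)


def test_lloyd_reaches_dp_optimum_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(40):
        n = int(rng.integers(6, 31))
        k = int(rng.integers(2, 6))
        v = _series(rng.normal(1.0, 0.3, size=n))
        lloyd = kmeans_1d(v, k, n_restarts=20, seed=int(rng.integers(2**31 - 1)))
        dp = dp_kmeans_1d(v, k)
        assert lloyd.inertia == pytest.approx(dp.inertia, rel=1e-9, abs=1e-12)


def test_k_exceeding_distinct_values_errors():
    v = _series([1.0, 1.0, 2.0])
    with pytest.raises(ClusterError, match="distinct"):
        kmeans_1d(v, 3, seed=0)
    with pytest.raises(ClusterError, match="distinct"):
        dp_kmeans_1d(v, 3)


def test_cluster_labels_invariant_under_input_permutation():
    rng = np.random.default_rng(9)
    v = _series(rng.normal(1, 0.2, 20))
    shuffled = v.sample(frac=1.0, random_state=3)
    a = dp_kmeans_1d(v, 4).assignment.sort_index()
    b = dp_kmeans_1d(shuffled, 4).assignment.sort_index()
    pd.testing.assert_series_equal(a, b)


@pytest.mark.parametrize("true_k", [2, 3, 4, 5, 6])
def test_vfold_recovers_planted_k_on_point_mass_levels(true_k):
    levels = np.linspace(0.5, 1.5, true_k)
    sizes = np.array_split(np.arange(74), true_k)
    v = _series(np.concatenate([np.full(len(s), levels[i]) for i, s in enumerate(sizes)]))
    trace = select_k_vfold(v, seed=5)
    assert trace.chosen_k == true_k


def test_vfold_two_levels_stops_at_two():
    v = _series(np.r_[np.full(40, 0.5), np.full(34, 1.3)])
    trace = select_k_vfold(v, k_candidates=range(2, 9), seed=3)
    assert trace.chosen_k == 2


def test_vfold_structureless_cloud_absorbs_noise_up_to_kmax():
    """A single Gaussian cloud has no distortion elbow: splitting any Gaussian
    cluster keeps improving held-out distortion by ~40-60%, so the
    threshold rule runs to the top candidate.  Documented limitation."""
    rng = np.random.default_rng(0)
    v = _series(rng.normal(1.0, 0.02, 74))
    trace = select_k_vfold(v, seed=3)
    assert trace.chosen_k == max(trace.candidates)


def test_vfold_identical_values_degenerate_error():
    v = _series(np.full(74, 1.0))
    with pytest.raises(ClusterError, match="degenerate"):
        select_k_vfold(v, seed=0)


def test_label_extremes_counts_against_atlas_classes(atlas):
    v = pd.Series(
        {"medulla": 0.5, "red_nucleus_L": 0.51, "red_nucleus_R": 0.52,
         "rectus_L": 0.53,  # cortical member of the hypo cluster
         "cingulate_L": 1.0, "cingulate_R": 1.01,
         "putamen_L": 1.5, "putamen_R": 1.51}
    )
    sol = dp_kmeans_1d(v, 3)
    hypo, hyper, counts = label_extremes(sol, atlas)
    assert hypo == {"medulla", "red_nucleus_L", "red_nucleus_R", "rectus_L"}
    assert counts[("hypo", "n")] == 4
    assert counts[("hypo", "n_subc")] == 3
    assert hyper == {"putamen_L", "putamen_R"}
    assert counts[("hyper", "n_subc")] == 2
    with pytest.raises(ClusterError, match="k >= 2"):
        label_extremes(dp_kmeans_1d(v, 1), atlas)


def test_planted_extremes_recovered_in_noisy_cohort(noisy_cohort, noisy_vectors, atlas):
    """>= 95% of planted hypo/hyper structures land in the five-cluster
    extremes on interictal scans at observation noise sd 0.02."""
    truth = noisy_cohort.truth.query("state == 'interictal'")
    total = recovered = 0
    for pid in noisy_cohort.patients:
        side = noisy_cohort.clinical.loc[pid, "onset_side"]
        t = truth[truth.patient == pid].set_index("structure")
        sol = cluster_scan(noisy_vectors[(pid, "interictal")].values, 5, seed=1)
        hypo, hyper, _ = label_extremes(sol, atlas)
        for level, ext in (("hypo", hypo), ("hyper", hyper)):
            planted = {atlas.ipsicontra_name(n, side) for n in t[t.level == level].index}
            total += len(planted)
            recovered += len(planted & ext)
    assert recovered / total >= 0.95
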