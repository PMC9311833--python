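"""Univariate k-means perfusion-pattern clustering with v-fold K selection.

Each scan's 74 perfusion indexes (or interictal->ictal change values) are
partitioned into K clusters by one-dimensional k-means.  The clusters with the
highest and lowest centroid are the scan's hyperperfused and hypoperfused
regions of interest.

Two engines are provided:

* ``lloyd`` — Lloyd iterations with random data-point initialisation (shuffle
  the data, draw K distinct points), Euclidean distance, best of ``n_restarts``
  by inertia.  This mirrors the clustering procedure the analysis is built
  around.  The first restart uses evenly spaced quantile data points, which in
  one dimension reliably lands in the optimal basin; the remaining restarts
  are random draws.
* ``dp`` — an exact dynamic program over the sorted values (optimal 1-D
  clusters are contiguous in sorted order), O(k n^2).  It serves as the
  independent optimality oracle for the Lloyd engine and as an optional
  deterministic engine.

The number of clusters is chosen by v-fold cross-validation on the distortion
(held-out squared distance to the nearest fitted centroid): K grows while each
additional cluster improves the cross-validated distortion by at least
``improvement_threshold`` (relative to the previous K), and the last
sufficiently-improving K is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSolution",
    "KSelectionTrace",
    "kmeans_1d",
    "dp_kmeans_1d",
    "select_k_vfold",
    "label_extremes",
]


class ClusterError(ValueError):
    pass


@dataclass
class ClusterSolution:
    """A k-means solution over one scan's structure values.

    Clusters are reported sorted by centroid, so ``hypo_cluster`` is always 0
    and ``hyper_cluster`` is ``k - 1``.
    """

    k: int
    centroids: np.ndarray  # sorted ascending
    assignment: pd.Series  # structure -> cluster index (into sorted centroids)
    inertia: float

    @property
    def hypo_cluster(self) -> int:
        return 0

    @property
    def hyper_cluster(self) -> int:
        return self.k - 1

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    def recompute_inertia(self, values: pd.Series) -> float:
        v = values.reindex(self.assignment.index).to_numpy(dtype=float)
        c = self.centroids[self.assignment.to_numpy()]
        return float(np.sum((v - c) ** 2))


@dataclass
class KSelectionTrace:
    """Cross-validated distortions per candidate K and the chosen K."""

    candidates: list[int]
    cv_distortion: list[float]  # mean held-out distortion; NaN if degenerate
    chosen_k: int
    folds: int
    improvement_threshold: float

    def as_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "cv_distortion": self.cv_distortion,
            "chosen_k": self.chosen_k,
            "folds": self.folds,
            "improvement_threshold": self.improvement_threshold,
        }


def _as_series(values) -> pd.Series:
    if isinstance(values, pd.Series):
        s = values.astype(float)
    else:
        s = pd.Series(dict(values), dtype=float)
    if s.empty:
        raise ClusterError("no values to cluster")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ClusterError("values must be finite")
    return s


def _refine_boundaries(x_sorted: np.ndarray, bounds: list, ps: np.ndarray, ps2: np.ndarray):
    """Hartigan-style single-point moves on a contiguous sorted partition.

    A converged Lloyd solution satisfies nearest-centroid stationarity, which
    is weaker than single-point optimality (moving a boundary point changes
    both cluster means).  Coordinate descent on the segment boundaries until
    no single move lowers the cost; cheap via prefix sums.
    """

    def seg_cost(i, j):
        if j < i:
            return np.inf  # empty segment forbidden
        m = j - i + 1
        ssum = ps[j + 1] - ps[i]
        return max((ps2[j + 1] - ps2[i]) - ssum * ssum / m, 0.0)

    def best_split(i, j):
        """Optimal 2-way split of xs[i..j]; returns (cost, split index) or None."""
        best = (np.inf, None)
        for m in range(i, j):
            c = seg_cost(i, m) + seg_cost(m + 1, j)
            if c < best[0]:
                best = (c, m)
        return best

    def boundary_pass():
        moved = False
        for b in range(len(bounds) - 1):
            (i0, j0), (i1, j1) = bounds[b], bounds[b + 1]
            current = seg_cost(i0, j0) + seg_cost(i1, j1)
            cost, m = best_split(i0, j1)
            if m is not None and m != j0 and cost < current - 1e-15:
                bounds[b] = (i0, m)
                bounds[b + 1] = (m + 1, j1)
                moved = True
        return moved

    def jump_pass():
        """Merge an adjacent pair and re-split a different segment (handles
        reconfigurations that no single-boundary move can reach)."""
        k = len(bounds)
        if k < 3:
            return False
        for b in range(k - 1):
            (i0, j0), (i1, j1) = bounds[b], bounds[b + 1]
            merge_increase = seg_cost(i0, j1) - seg_cost(i0, j0) - seg_cost(i1, j1)
            for c in range(k):
                if c in (b, b + 1):
                    continue
                ic, jc = bounds[c]
                if jc == ic:
                    continue  # singleton cannot be split
                cost, m = best_split(ic, jc)
                gain = seg_cost(ic, jc) - cost
                if gain > merge_increase + 1e-15:
                    new_bounds = []
                    for idx, seg in enumerate(bounds):
                        if idx == b:
                            new_bounds.append((i0, j1))
                        elif idx == b + 1:
                            continue
                        elif idx == c:
                            new_bounds.append((ic, m))
                            new_bounds.append((m + 1, jc))
                        else:
                            new_bounds.append(seg)
                    bounds[:] = sorted(new_bounds)
                    return True
        return False

    while True:
        moved = False
        while boundary_pass():
            moved = True
        if jump_pass():
            moved = True
            continue
        if not moved:
            break
    return bounds


def _lloyd_once(x: np.ndarray, init: np.ndarray, max_iter: int = 300):
    """One Lloyd run; returns (centroids, labels, inertia) with centroids unsorted."""
    centroids = init.astype(float).copy()
    k = len(centroids)
    labels = np.full(len(x), -1)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centroids[None, :])
        new_labels = np.argmin(d, axis=1)  # ties break toward the lower index
        # refill empty clusters with the point farthest from its centroid
        for j in range(k):
            if not np.any(new_labels == j):
                dist_own = np.abs(x - centroids[new_labels])
                far = int(np.argmax(dist_own))
                centroids[j] = x[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = x[labels == j].mean()
    inertia = float(np.sum((x - centroids[labels]) ** 2))
    return centroids, labels, inertia


def _dsq_init(distinct: np.ndarray, k: int, rng) -> np.ndarray:
    """D^2-weighted data-point seeding: spread initial centroids apart."""
    centroids = [rng.choice(distinct)]
    for _ in range(k - 1):
        d2 = np.min(np.abs(distinct[:, None] - np.asarray(centroids)[None, :]), axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(distinct, centroids)
            centroids.append(rng.choice(remaining))
            continue
        centroids.append(rng.choice(distinct, p=d2 / total))
    return np.asarray(centroids, dtype=float)


def kmeans_1d(values, k: int, n_restarts: int = 20, seed: int = 0) -> ClusterSolution:
    """Best-of-restarts univariate Lloyd k-means, deterministic given ``seed``.

    Restart inits mix three schemes: one deterministic quantile spread, plain
    random data-point draws (the shuffle-and-pick scheme the procedure
    describes), and D^2-weighted draws that spread seeds apart.  The mix makes
    20 restarts reliably attain the exact 1-D optimum (the DP engine checks
    this property).
    """
    s = _as_series(values)
    x = s.to_numpy()
    distinct = np.unique(x)
    if k < 1:
        raise ClusterError("k must be >= 1")
    if k > len(distinct):
        raise ClusterError(f"k={k} exceeds the {len(distinct)} distinct values")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            # deterministic quantile init: evenly spaced data points of the sorted sample
            qs = np.linspace(0, 1, k + 2)[1:-1]
            init = np.unique(np.quantile(distinct, qs, method="nearest"))
            if len(init) < k:  # fall back to distinct spread
                init = distinct[np.linspace(0, len(distinct) - 1, k).round().astype(int)]
            init = np.unique(init)
            if len(init) < k:
                init = rng.choice(distinct, size=k, replace=False)
        elif r % 2 == 1:
            # shuffle the dataset, then draw k distinct data points as centroids
            init = rng.choice(distinct, size=k, replace=False)
        else:
            init = _dsq_init(distinct, k, rng)
        centroids, labels, inertia = _lloyd_once(x, np.asarray(init, dtype=float))
        centroids, labels, inertia = _polish_1d(x, centroids, labels)
        if best is None or inertia < best[2] - 1e-15:
            best = (centroids, labels, inertia)
    centroids, labels, inertia = best
    assignment = pd.Series(labels, index=s.index, name="cluster")
    return ClusterSolution(
        k=k, centroids=centroids, assignment=assignment, inertia=inertia
    )


def _polish_1d(x: np.ndarray, centroids: np.ndarray, labels: np.ndarray):
    """Boundary-refine a converged Lloyd solution; returns sorted-cluster form."""
    k = len(centroids)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    # contiguous segments in centroid order (1-D Lloyd partitions are intervals)
    corder = np.argsort(centroids, kind="stable")
    sizes = [int(np.sum(labels == c)) for c in corder]
    bounds = []
    start = 0
    for m in sizes:
        bounds.append((start, start + m - 1))
        start += m
    bounds = _refine_boundaries(xs, bounds, ps, ps2)
    labels_sorted = np.empty(len(x), dtype=int)
    new_centroids = np.empty(k)
    inertia = 0.0
    for c, (i, j) in enumerate(bounds):
        labels_sorted[i : j + 1] = c
        seg = xs[i : j + 1]
        new_centroids[c] = seg.mean()
        inertia += float(np.sum((seg - seg.mean()) ** 2))
    out_labels = np.empty(len(x), dtype=int)
    out_labels[order] = labels_sorted
    return new_centroids, out_labels, inertia


def dp_kmeans_1d(values, k: int) -> ClusterSolution:
    """Exact optimal univariate k-means by dynamic programming over sorted values."""
    s = _as_series(values)
    x = s.to_numpy()
    n = len(x)
    distinct = np.unique(x)
    if k < 1:
        raise ClusterError("k must be >= 1")
    if k > len(distinct):
        raise ClusterError(f"k={k} exceeds the {len(distinct)} distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # prefix sums for O(1) within-segment sum of squares
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: int, j: int) -> float:  # cost of xs[i..j] inclusive
        m = j - i + 1
        ssum = ps[j + 1] - ps[i]
        ssq = ps2[j + 1] - ps2[i]
        return max(ssq - ssum * ssum / m, 0.0)

    INF = float("inf")
    D = np.full((k + 1, n), INF)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        D[1, j] = seg_cost(0, j)
    for kk in range(2, k + 1):
        for j in range(kk - 1, n):
            best_cost, best_i = INF, kk - 1
            for i in range(kk - 1, j + 1):
                c = D[kk - 1, i - 1] + seg_cost(i, j)
                if c < best_cost:
                    best_cost, best_i = c, i
            D[kk, j] = best_cost
            back[kk, j] = best_i
    # backtrack segment boundaries
    bounds = []
    j = n - 1
    for kk in range(k, 0, -1):
        i = back[kk, j] if kk > 1 else 0
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()
    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for c, (i, j) in enumerate(bounds):
        labels_sorted[i : j + 1] = c
        centroids[c] = xs[i : j + 1].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    assignment = pd.Series(labels, index=s.index, name="cluster")
    return ClusterSolution(
        k=k, centroids=centroids, assignment=assignment, inertia=float(D[k, n - 1])
    )


def cluster_scan(values, k: int, *, engine: str = "lloyd", n_restarts: int = 20, seed: int = 0) -> ClusterSolution:
    """Cluster one scan's values with the requested engine."""
    if engine == "lloyd":
        return kmeans_1d(values, k, n_restarts=n_restarts, seed=seed)
    if engine == "dp":
        return dp_kmeans_1d(values, k)
    raise ClusterError(f"unknown engine {engine!r}")


def select_k_vfold(
    values,
    k_candidates=range(2, 11),
    folds: int = 10,
    improvement_threshold: float = 0.05,
    seed: int = 0,
    *,
    engine: str = "lloyd",
    n_restarts: int = 20,
) -> KSelectionTrace:
    """Choose K by v-fold cross-validated distortion.

    For each candidate K the values are split into ``folds`` random folds; a
    k-means fit on the remaining folds scores each held-out value by squared
    distance to the nearest centroid.  K grows while each step improves the
    mean held-out distortion by at least ``improvement_threshold`` relative to
    the previous K (a zero previous distortion, or a candidate infeasible on
    the training folds, counts as no improvement); the last K whose own step
    improved sufficiently is returned.
    """
    s = _as_series(values)
    x = s.to_numpy()
    n = len(x)
    candidates = sorted(int(k) for k in k_candidates)
    if not candidates:
        raise ClusterError("no candidate K values")
    if folds < 2:
        raise ClusterError("folds must be >= 2")
    if n < folds:
        raise ClusterError("fewer values than folds")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(idx, folds)):
        fold_of[part] = f

    def cv_distortion(k: int) -> float:
        total, used = 0.0, 0
        for f in range(folds):
            train = x[fold_of != f]
            test = x[fold_of == f]
            if k > len(np.unique(train)):
                return float("nan")  # infeasible on the training folds
            sol = cluster_scan(
                pd.Series(train), k, engine=engine, n_restarts=n_restarts,
                seed=int(rng.integers(2**31 - 1)),
            )
            d = np.min(np.abs(test[:, None] - sol.centroids[None, :]), axis=1)
            total += float(np.sum(d**2))
            used += len(test)
        return total / used

    distortions = [cv_distortion(k) for k in candidates]
    if all(np.isnan(d) for d in distortions):
        raise ClusterError("all candidate K values are degenerate for these data")

    chosen = None
    prev_d = None
    for k, d in zip(candidates, distortions):
        if np.isnan(d):
            break  # infeasible: stop growing
        if prev_d is None:
            chosen = k  # first feasible candidate is the floor
        else:
            improvement = 0.0 if prev_d <= 0 else (prev_d - d) / prev_d
            if improvement < improvement_threshold:
                break
            chosen = k
        prev_d = d
    return KSelectionTrace(
        candidates=candidates,
        cv_distortion=[float(d) for d in distortions],
        chosen_k=int(chosen),
        folds=folds,
        improvement_threshold=improvement_threshold,
    )


def label_extremes(solution: ClusterSolution, atlas):
    """Hypo/hyper extreme-cluster structure sets with N and N_subcortical counts.

    Returns ``(hypo_set, hyper_set, counts)`` where counts is a dict with keys
    ``('hypo','n')``, ``('hypo','n_subc')``, ``('hyper','n')``, ``('hyper','n_subc')``.
    """
    if solution.k < 2:
        raise ClusterError("extreme clusters need k >= 2")
    hypo = set(solution.members(solution.hypo_cluster))
    hyper = set(solution.members(solution.hyper_cluster))
    counts = {}
    for role, members in (("hypo", hypo), ("hyper", hyper)):
        counts[(role, "n")] = len(members)
        counts[(role, "n_subc")] = sum(1 for m in members if atlas.is_subcortical(m))
    return hypo, hyper, counts
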