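"""k-medoids clustering of horizon subsets and benthic-envelope extraction.

Record depths within a horizon subset are min-max normalised and clustered
with partitioning around medoids (PAM).  Exact PAM (greedy BUILD followed by
best-improvement SWAP, which for the small instances tested here reaches the
global optimum) is used up to ``pam_threshold`` points; above that the CLARA
strategy clusters seeded subsamples and keeps the candidate medoid set with
the lowest full-data cost.  The number of clusters is chosen by maximising
the average silhouette width (ASW) over k = 2..10, and the cluster whose
depth range contains the horizon's seabed depth is taken as the benthic data
cloud; its min/max record depths form the horizon envelope.

All tie-breaks are deterministic (first/lowest index wins) and all
randomness flows through an explicit seed, so identical inputs give
bitwise-identical solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from benthicsplit.horizons import DepthHorizon, HorizonSubset

__all__ = [
    "ClusterSolution",
    "HorizonEnvelope",
    "benthic_envelope",
    "clara_cluster",
    "cluster_horizon",
    "identify_benthic_cluster",
    "normalize01",
    "pam_exact",
    "silhouette_asw",
    "sweep_k",
]

_SWAP_TOL = 1e-12
_MAX_SWAP_ITER = 500


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterSolution:
    """A k-medoids partition of one subset's (normalised) depths."""

    k: int
    labels: np.ndarray          # (n,) cluster id in [0, k)
    medoid_indices: np.ndarray  # (k,) indices into the clustered points
    medoids: np.ndarray         # (k,) or (k, d) medoid coordinates
    cost: float                 # sum of point-to-own-medoid distances
    asw: float | None = None


@dataclass
class HorizonEnvelope:
    """Benthic min/max record depth (metres) for one horizon."""

    horizon: DepthHorizon
    benthic_min_m: float
    benthic_max_m: float
    chosen_k: int
    asw_by_k: dict[int, float] = field(default_factory=dict)
    fallback: bool = False
    n_members: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.benthic_min_m <= self.benthic_max_m:
            raise ClusteringError(
                f"invalid envelope for {self.horizon.label}: "
                f"[{self.benthic_min_m}, {self.benthic_max_m}]"
            )


def normalize01(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; constant input maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ClusteringError("normalize01: empty input")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def _distance_matrix(points: np.ndarray) -> np.ndarray:
    pts = _as_points(points)
    if pts.shape[1] == 1:
        return np.abs(pts - pts.T)
    return cdist(pts, pts)


#: instance-size budget below which the optimal medoid set is enumerated
_ENUM_BUDGET = 3000


def _interval_cost_matrix(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cost of serving each sorted interval [i..j] from its (lower) median.

    Returns ``(C, M)``: C[i, j] is the sum of absolute deviations from the
    interval's lower median, M[i, j] that median's index; entries with
    i > j are +inf.
    """
    n = xs.size
    S = np.concatenate([[0.0], np.cumsum(xs)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = (i + j) // 2  # lower median index
    left = xs[m] * (m - i) - (S[m] - S[i])
    right = (S[j + 1] - S[m + 1]) - xs[m] * (j - m)
    C = left + right
    C[i > j] = np.inf
    return C, m


def _pam_1d_all_k(points: np.ndarray, kmax: int) -> dict[int, ClusterSolution]:
    """Globally optimal 1-D k-medoids for every k in 1..kmax, by one DP pass.

    In one dimension the optimal partition is contiguous in sorted order and
    each segment is best served by its median, so a segment DP over the
    interval-cost matrix yields the exact optimum; each DP layer is the
    solution for one more cluster, so a whole k sweep costs one O(kmax n^2)
    pass.
    """
    x = np.asarray(points, dtype=float).ravel()
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    C, M = _interval_cost_matrix(xs)

    # dp[j] = best cost of covering sorted points 0..j with t clusters
    dp = C[0].copy()
    splits: list[np.ndarray] = []  # start index of the last segment per layer
    solutions: dict[int, ClusterSolution] = {}
    for t in range(1, kmax + 1):
        if t > 1:
            cand = C[1:, :] + dp[:-1, None]  # cand[i-1, j] = dp[i-1] + C[i, j]
            start = cand.argmin(axis=0) + 1
            dp = cand[start - 1, np.arange(n)]
            splits.append(start)
        # backtrack segment boundaries for exactly t clusters
        bounds = []
        j = n - 1
        for c in range(t - 1, 0, -1):
            i = int(splits[c - 1][j])
            bounds.append((i, j))
            j = i - 1
        bounds.append((0, j))
        bounds.reverse()
        med_sorted = np.array([int(M[i, j]) for i, j in bounds], dtype=np.int64)
        med = np.sort(order[med_sorted])
        diffs = np.abs(x[None, :] - x[med][:, None])
        labels = diffs.argmin(axis=0)
        cost = float(diffs[labels, np.arange(n)].sum())
        solutions[t] = ClusterSolution(
            k=t, labels=labels, medoid_indices=med, medoids=np.asarray(points)[med], cost=cost
        )
    return solutions


def _pam_1d_optimal(points: np.ndarray, k: int) -> ClusterSolution:
    return _pam_1d_all_k(points, k)[k]


def pam_exact(
    points: np.ndarray, k: int, dist: np.ndarray | None = None
) -> ClusterSolution:
    """Partitioning around medoids, exact wherever tractable.

    1-D inputs (the pipeline's normalised record depths) are solved to the
    global optimum by a sorted-order dynamic program.  Multivariate inputs
    use direct enumeration of medoid sets when ``C(n, k)`` is small and the
    classic greedy BUILD + best-improvement SWAP search otherwise.
    Deterministic: all ties resolve to the lowest index.  ``dist`` may carry
    a precomputed pairwise distance matrix (reused across a k sweep).
    """
    from math import comb

    pts = _as_points(points)
    n = pts.shape[0]
    if k < 1:
        raise ClusteringError(f"k must be >= 1, got {k}")
    if k > n:
        raise ClusteringError(f"k={k} exceeds number of points n={n}")
    if pts.shape[1] == 1:
        return _pam_1d_optimal(points, k)
    D = _distance_matrix(points) if dist is None else dist

    if comb(n, k) <= _ENUM_BUDGET:
        from itertools import combinations

        best_med, best_cost = None, np.inf
        for med in combinations(range(n), k):
            cost = D[list(med)].min(axis=0).sum()
            if cost < best_cost - _SWAP_TOL:
                best_med, best_cost = med, cost
        med = np.array(best_med, dtype=np.int64)
        dd = D[med]
        labels = dd.argmin(axis=0)
        return ClusterSolution(
            k=k,
            labels=labels,
            medoid_indices=med,
            medoids=np.asarray(points)[med],
            cost=float(dd[labels, np.arange(n)].sum()),
        )

    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # giving the largest cost reduction.
    medoids = [int(D.sum(axis=1).argmin())]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(gains.argmax())
        medoids.append(h)
        np.minimum(d_near, D[h], out=d_near)

    med = np.array(medoids, dtype=np.int64)

    # SWAP: evaluate every (medoid m, candidate h) exchange in O(n^2) per
    # iteration via the nearest/second-nearest decomposition.
    for _ in range(_MAX_SWAP_ITER):
        dd = D[med]                       # (k, n)
        n1 = dd.argmin(axis=0)            # index into med
        d1 = dd[n1, np.arange(n)]
        d2 = np.partition(dd, 1, axis=0)[1] if k > 1 else np.full(n, np.inf)
        base = np.minimum(D, d1[None, :])
        delta_add = base.sum(axis=1) - d1.sum()          # (n,) gain of adding h
        corr = np.minimum(D, d2[None, :]) - base         # (n, n) >= 0
        deltas = np.empty((n, k))
        for m in range(k):
            deltas[:, m] = delta_add + corr[:, n1 == m].sum(axis=1)
        deltas[med, :] = np.inf
        flat = int(deltas.argmin())
        h, m = divmod(flat, k)
        if deltas[h, m] >= -_SWAP_TOL:
            break
        med[m] = h

    med = np.sort(med)
    dd = D[med]
    labels = dd.argmin(axis=0)
    cost = float(dd[labels, np.arange(n)].sum())
    return ClusterSolution(
        k=k, labels=labels, medoid_indices=med, medoids=np.asarray(points)[med], cost=cost
    )


def clara_cluster(
    points: np.ndarray,
    k: int,
    n_subsamples: int = 5,
    subsample_size: int | None = None,
    seed: int | None = None,
) -> ClusterSolution:
    """CLARA: best-of-subsamples PAM for large n.

    Each seeded subsample is clustered with :func:`pam_exact`; all points are
    then assigned to the nearest candidate medoid and the medoid set with the
    lowest full-data cost wins.  With ``n_subsamples=1`` and
    ``subsample_size=n`` this reduces exactly to :func:`pam_exact`.  Default
    subsample size is the classic ``min(n, 40 + 2k)`` heuristic.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if k < 1:
        raise ClusteringError(f"k must be >= 1, got {k}")
    if k > n:
        raise ClusteringError(f"k={k} exceeds number of points n={n}")
    if subsample_size is None:
        subsample_size = min(n, 40 + 2 * k)
    if subsample_size > n:
        raise ClusteringError("subsample_size exceeds number of points")
    if subsample_size < k:
        raise ClusteringError("subsample_size must be >= k")
    rng = np.random.default_rng(seed)

    best: ClusterSolution | None = None
    for _ in range(n_subsamples):
        if subsample_size == n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=subsample_size, replace=False))
        sub = pam_exact(pts[idx], k)
        med = np.sort(idx[sub.medoid_indices])
        dd = cdist(pts[med], pts) if pts.shape[1] > 1 else np.abs(pts[med] - pts.T)
        labels = dd.argmin(axis=0)
        cost = float(dd[labels, np.arange(n)].sum())
        if best is None or cost < best.cost:
            best = ClusterSolution(
                k=k,
                labels=labels,
                medoid_indices=med,
                medoids=np.asarray(points)[med],
                cost=cost,
            )
    assert best is not None
    return best


def silhouette_asw(
    points: np.ndarray,
    labels: np.ndarray,
    dist: np.ndarray | None = None,
) -> float:
    """Average silhouette width of a partition.

    For each point, ``s = (b - a) / max(a, b)`` with ``a`` the mean distance
    to its own cluster (excluding itself) and ``b`` the smallest mean
    distance to any other cluster; singleton clusters contribute ``s = 0``.
    """
    labels = np.asarray(labels)
    n = labels.size
    ids, inv, sizes = np.unique(labels, return_inverse=True, return_counts=True)
    if ids.size < 2:
        raise ClusteringError("silhouette undefined for k=1")
    D = _distance_matrix(points) if dist is None else dist
    # mean distance from every point to every cluster
    sums = np.zeros((n, ids.size))
    for c in range(ids.size):
        sums[:, c] = D[:, inv == c].sum(axis=1)
    own = inv
    a = np.zeros(n)
    nonsingle = sizes[own] > 1
    a[nonsingle] = sums[np.arange(n), own][nonsingle] / (sizes[own][nonsingle] - 1)
    means_other = sums / sizes[None, :]
    means_other[np.arange(n), own] = np.inf
    b = means_other.min(axis=1)
    s = np.zeros(n)
    denom = np.maximum(a, b)
    ok = nonsingle & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(s.mean())


def sweep_k(
    points: np.ndarray,
    kmin: int = 2,
    kmax: int = 10,
    seed: int | None = None,
    pam_threshold: int = 2000,
    n_subsamples: int = 5,
    subsample_size: int | None = None,
    asw_sample_size: int = 2000,
) -> tuple[ClusterSolution, dict[int, float]]:
    """Cluster for each k in [kmin, min(kmax, n-1)] and pick the max-ASW solution.

    Ties break toward smaller k.  Up to ``pam_threshold`` points the pairwise
    distance matrix is computed once and shared by exact PAM and the
    silhouette; above it CLARA is used and the ASW is evaluated on a seeded
    subsample of ``asw_sample_size`` points.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n <= kmin:
        raise ClusteringError(f"need more than kmin={kmin} points, got {n}")
    kmax_eff = min(kmax, n - 1)
    rng = np.random.default_rng(seed)

    exact = n <= pam_threshold
    if exact:
        D = _distance_matrix(pts)
        asw_idx = None
        exact_1d = {} if pts.shape[1] > 1 else _pam_1d_all_k(points, kmax_eff)
    else:
        D = None
        asw_idx = np.sort(rng.choice(n, size=min(n, asw_sample_size), replace=False))
        D_sub = _distance_matrix(pts[asw_idx])

    best: ClusterSolution | None = None
    asw_by_k: dict[int, float] = {}
    for k in range(kmin, kmax_eff + 1):
        if exact:
            sol = exact_1d.get(k) or pam_exact(pts, k, dist=D)
            asw = silhouette_asw(pts, sol.labels, dist=D)
        else:
            child = int(rng.integers(2**31))
            sol = clara_cluster(pts, k, n_subsamples, subsample_size, seed=child)
            sub_labels = sol.labels[asw_idx]
            if np.unique(sub_labels).size < 2:
                asw = -1.0  # subsample missed all but one cluster
            else:
                asw = silhouette_asw(pts[asw_idx], sub_labels, dist=D_sub)
        sol.asw = asw
        asw_by_k[k] = asw
        if best is None or asw > best.asw:
            best = sol
    assert best is not None
    return best, asw_by_k


def identify_benthic_cluster(
    solution: ClusterSolution,
    points: np.ndarray,
    horizon_target_norm: float,
) -> tuple[int, bool]:
    """Find the cluster representing the benthic data cloud.

    Returns the cluster whose closed [min, max] range of (normalised) depths
    contains the horizon's seabed depth; when no cluster contains it the
    cluster with the medoid nearest the target is returned and the fallback
    flag is set.  If several ranges contain the target (shared boundary
    point) the nearest-medoid cluster among them wins.
    """
    pts = np.asarray(points, dtype=float).ravel()
    med = np.asarray(solution.medoids, dtype=float).ravel()
    containing = [
        c
        for c in range(solution.k)
        if pts[solution.labels == c].min() <= horizon_target_norm <= pts[solution.labels == c].max()
    ]
    if containing:
        dist = np.abs(med[containing] - horizon_target_norm)
        return int(containing[int(dist.argmin())]), False
    return int(np.abs(med - horizon_target_norm).argmin()), True


def benthic_envelope(
    subset: HorizonSubset,
    benthic_cluster_members: np.ndarray,
    chosen_k: int = 0,
    asw_by_k: dict[int, float] | None = None,
    fallback: bool = False,
) -> HorizonEnvelope:
    """Envelope (min/max record depth, metres) of the benthic cluster's members.

    ``benthic_cluster_members`` is a boolean mask or index array into
    ``subset.records``.
    """
    depths = subset.records["record_depth_m"].to_numpy(dtype=float)[benthic_cluster_members]
    if depths.size == 0:
        raise ClusteringError(f"horizon {subset.horizon.label}: empty benthic cluster")
    return HorizonEnvelope(
        horizon=subset.horizon,
        benthic_min_m=float(depths.min()),
        benthic_max_m=float(depths.max()),
        chosen_k=chosen_k,
        asw_by_k=asw_by_k or {},
        fallback=fallback,
        n_members=int(depths.size),
    )


def cluster_horizon(
    subset: HorizonSubset,
    kmin: int = 2,
    kmax: int = 10,
    seed: int | None = None,
    k_override: int | None = None,
    pam_threshold: int = 2000,
    n_subsamples: int = 5,
    subsample_size: int | None = None,
) -> tuple[HorizonEnvelope, ClusterSolution]:
    """Full clustering stage for one trimmed horizon subset.

    Normalises record depths, sweeps k (or uses ``k_override``, the hook for
    reproducing expert-chosen solutions), identifies the benthic cluster via
    the horizon's normalised seabed depth and extracts its envelope.
    """
    depths = subset.records["record_depth_m"].to_numpy(dtype=float)
    if depths.size == 0:
        raise ClusteringError(f"horizon {subset.horizon.label}: empty subset")
    lo, hi = depths.min(), depths.max()
    if hi == lo:
        raise ClusteringError(
            f"horizon {subset.horizon.label}: all record depths equal; cannot cluster"
        )
    norm = normalize01(depths)
    target_norm = (subset.horizon.target_depth_m - lo) / (hi - lo)

    if k_override is not None:
        if depths.size <= pam_threshold:
            sol = pam_exact(norm, k_override)
            sol.asw = silhouette_asw(norm, sol.labels)
        else:
            sol = clara_cluster(norm, k_override, n_subsamples, subsample_size, seed=seed)
        asw_by_k = {k_override: sol.asw if sol.asw is not None else float("nan")}
    else:
        sol, asw_by_k = sweep_k(
            norm,
            kmin,
            kmax,
            seed=seed,
            pam_threshold=pam_threshold,
            n_subsamples=n_subsamples,
            subsample_size=subsample_size,
        )
    cluster_id, fallback = identify_benthic_cluster(sol, norm, target_norm)
    env = benthic_envelope(
        subset,
        sol.labels == cluster_id,
        chosen_k=sol.k,
        asw_by_k=asw_by_k,
        fallback=fallback,
    )
    return env, sol
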