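"""k-medoids, silhouette and benthic-envelope extraction.

Oracles: exhaustive medoid-set enumeration for PAM global optimality, and a
direct per-point evaluation of the silhouette definition.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthicsplit import (
    DepthHorizon,
    benthic_envelope,
    clara_cluster,
    identify_benthic_cluster,
    normalize01,
    pam_exact,
    silhouette_asw,
    sweep_k,
)
from benthicsplit.clustering import ClusteringError
from benthicsplit.horizons import HorizonSubset

from conftest import make_records


def exhaustive_pam_cost(points, k):
    """Global-minimum PAM cost by enumerating all medoid sets (oracle)."""
    pts = np.asarray(points, dtype=float)
    D = np.abs(pts[:, None] - pts[None, :])
    return min(
        D[list(med)].min(axis=0).sum() for med in itertools.combinations(range(len(pts)), k)
    )


def brute_silhouette(points, labels):
    """Direct evaluation of the silhouette definition, one point at a time (oracle)."""
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    s_vals = []
    for i in range(len(pts)):
        own = labels == labels[i]
        if own.sum() == 1:
            s_vals.append(0.0)
            continue
        a = np.mean([abs(pts[i] - pts[j]) for j in range(len(pts)) if own[j] and j != i])
        b = min(
            np.mean([abs(pts[i] - pts[j]) for j in range(len(pts)) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        s_vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(s_vals))


class TestNormalize01:
    def test_example(self):
        np.testing.assert_allclose(normalize01(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(normalize01(np.array([7.0, 7.0, 7.0])), [0, 0, 0])

    def test_empty_errors(self):
        with pytest.raises(ClusteringError):
            normalize01(np.array([]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=50)
    )
    def test_order_preserving_and_bounded(self, values):
        arr = np.array(values)
        out = normalize01(arr)
        assert out.min() >= 0 and out.max() <= 1
        # monotone map: sorting by input value gives non-decreasing output
        assert np.all(np.diff(out[np.argsort(arr, kind="stable")]) >= 0)


class TestPamExact:
    def test_two_pairs(self):
        sol = pam_exact(np.array([1.0, 2.0, 10.0, 11.0]), 2)
        assert sol.cost == pytest.approx(2.0)
        assert sol.labels[0] == sol.labels[1] != sol.labels[2] == sol.labels[3]
        assert sol.cost == pytest.approx(exhaustive_pam_cost([1, 2, 10, 11], 2))

    def test_k_equals_n_zero_cost(self):
        pts = np.array([3.0, 1.0, 7.0, 9.0])
        sol = pam_exact(pts, 4)
        assert sol.cost == 0.0
        assert len(np.unique(sol.labels)) == 4

    def test_k1_constant(self):
        assert pam_exact(np.array([0.0, 0.0, 0.0]), 1).cost == 0.0

    @pytest.mark.parametrize("k", [0, 5])
    def test_invalid_k(self, k):
        with pytest.raises(ClusteringError):
            pam_exact(np.array([1.0, 2.0, 3.0]), k)

    def test_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 4))
            pts = rng.uniform(0, 1, n)
            sol = pam_exact(pts, k)
            assert sol.cost == pytest.approx(exhaustive_pam_cost(pts, k), abs=1e-12)

    def test_1d_clusters_are_contiguous(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.uniform(0, 1, 80)
            sol = pam_exact(pts, int(rng.integers(2, 6)))
            order = np.argsort(pts)
            runs = np.unique(sol.labels[order][np.r_[True, np.diff(sol.labels[order]) != 0]])
            # sorted labels form k non-interleaved runs
            assert len(runs) == sol.k

    def test_medoids_are_members(self):
        pts = np.random.default_rng(5).uniform(0, 1, 30)
        sol = pam_exact(pts, 3)
        for c in range(3):
            assert sol.labels[sol.medoid_indices[c]] == c


class TestClara:
    def test_full_sampling_reduces_to_pam(self):
        pts = np.random.default_rng(1).uniform(0, 1, 60)
        pam = pam_exact(pts, 3)
        clara = clara_cluster(pts, 3, n_subsamples=1, subsample_size=60, seed=9)
        assert np.array_equal(pam.labels, clara.labels)
        assert np.array_equal(pam.medoid_indices, clara.medoid_indices)
        assert pam.cost == clara.cost

    def test_same_seed_identical(self):
        pts = np.random.default_rng(2).uniform(0, 1, 500)
        a = clara_cluster(pts, 3, seed=7)
        b = clara_cluster(pts, 3, seed=7)
        assert np.array_equal(a.labels, b.labels) and a.cost == b.cost

    def test_blob_recovery(self):
        rng = np.random.default_rng(8)
        blob = np.concatenate([rng.normal(0.1, 0.02, 5000), rng.normal(0.9, 0.02, 5000)])
        truth = np.repeat([0, 1], 5000)
        sol = clara_cluster(blob, 2, seed=13)
        # align labels to truth
        agree = max(np.mean(sol.labels == truth), np.mean(sol.labels == 1 - truth))
        assert agree >= 0.99


class TestSilhouette:
    def test_hand_example_with_singleton(self):
        pts = np.array([0.0, 0.1, 1.0])
        labels = np.array([0, 0, 1])
        expected = (0.9 + (0.9 - 0.1) / 0.9 + 0.0) / 3
        assert silhouette_asw(pts, labels) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5963, abs=5e-5)

    def test_tight_far_clusters_approach_one(self):
        pts = np.concatenate([np.full(5, 0.0) + 1e-6 * np.arange(5), np.full(5, 1.0)])
        labels = np.repeat([0, 1], 5)
        assert silhouette_asw(pts, labels) > 0.999

    def test_single_cluster_errors(self):
        with pytest.raises(ClusteringError, match="k=1"):
            silhouette_asw(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            k = int(rng.integers(2, 6))
            pts = rng.uniform(0, 1, n)
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette_asw(pts, labels) == pytest.approx(
                brute_silhouette(pts, labels), abs=1e-9
            )


class TestSweepK:
    def test_two_blob_selects_k2(self):
        rng = np.random.default_rng(4)
        pts = normalize01(
            np.concatenate([rng.normal(0.1, 0.02, 300), rng.normal(0.9, 0.02, 300)])
        )
        best, asw_by_k = sweep_k(pts, seed=0)
        assert best.k == 2
        assert asw_by_k[2] > 0.8

    def test_small_n_limits_range(self):
        pts = np.arange(8.0)
        _, asw_by_k = sweep_k(pts, kmin=2, kmax=10, seed=0)
        assert sorted(asw_by_k) == list(range(2, 8))

    def test_one_entry_per_k(self):
        pts = np.random.default_rng(0).uniform(0, 1, 50)
        _, asw_by_k = sweep_k(pts, kmin=2, kmax=6, seed=0)
        assert sorted(asw_by_k) == [2, 3, 4, 5, 6]


class TestIdentifyBenthicCluster:
    def _solution(self, pts, labels, medoids):
        from benthicsplit.clustering import ClusterSolution

        return ClusterSolution(
            k=len(medoids),
            labels=np.asarray(labels),
            medoid_indices=np.asarray(medoids),
            medoids=np.asarray(pts)[np.asarray(medoids)],
            cost=0.0,
        )

    def test_containing_cluster_wins(self):
        pts = np.array([0.85, 0.92, 1.0, 0.0, 0.15, 0.3])
        sol = self._solution(pts, [0, 0, 0, 1, 1, 1], [1, 4])
        cid, fallback = identify_benthic_cluster(sol, pts, 0.95)
        assert cid == 0 and not fallback

    def test_fallback_nearest_medoid(self):
        pts = np.array([0.85, 0.92, 1.0, 0.0, 0.15, 0.3])
        sol = self._solution(pts, [0, 0, 0, 1, 1, 1], [1, 4])
        cid, fallback = identify_benthic_cluster(sol, pts, 0.6)
        assert cid == 0 and fallback  # medoid 0.92 closer to 0.6 than 0.15

    def test_boundary_point_counts_as_contained(self):
        pts = np.array([0.2, 0.5, 0.8, 0.9])
        sol = self._solution(pts, [0, 0, 1, 1], [0, 3])
        cid, fallback = identify_benthic_cluster(sol, pts, 0.5)
        assert cid == 0 and not fallback


class TestBenthicEnvelope:
    def _subset(self, depths, target=1000.0):
        records = make_records(
            np.zeros(len(depths)), np.zeros(len(depths)), depths,
            seabed=np.full(len(depths), target),
        )
        return HorizonSubset(DepthHorizon(target, 10.0), records)

    def test_min_max_of_members(self):
        sub = self._subset([920.0, 950.0, 1020.0])
        env = benthic_envelope(sub, np.array([True, True, True]), chosen_k=2)
        assert (env.benthic_min_m, env.benthic_max_m) == (920.0, 1020.0)

    def test_singleton_cluster(self):
        sub = self._subset([990.0, 400.0])
        env = benthic_envelope(sub, np.array([True, False]))
        assert env.benthic_min_m == env.benthic_max_m == 990.0

    def test_empty_cluster_errors(self):
        with pytest.raises(ClusteringError, match="empty"):
            benthic_envelope(self._subset([990.0]), np.array([False]))

    def test_true_member_envelope_within_generator_truth(self):
        # members drawn as seabed - |noise|: envelope must sit in the truth range
        rng = np.random.default_rng(6)
        seabed = 2000.0
        depths = seabed - np.abs(rng.normal(0, 25, 200))
        env = benthic_envelope(self._subset(depths, target=seabed), np.ones(200, bool))
        assert seabed - 4 * 25 <= env.benthic_min_m <= env.benthic_max_m <= seabed
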