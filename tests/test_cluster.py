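"""Ward clustering, cluster-count selection and cluster comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import foragespec as fs
from foragespec.cluster import cut_labels, ward_cluster, choose_k
from foragespec.errors import InsufficientDataError


def greedy_ward_oracle(X):
    """Independent Ward agglomeration: at each step merge the pair whose union
    minimises the increase in within-cluster sum of squares, computed directly
    from cluster members.  Returns (list of merged partitions, heights)."""
    X = np.asarray(X, float)

    def wss(idx):
        pts = X[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [[i] for i in range(len(X))]
    partitions, heights = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = wss(clusters[i] + clusters[j]) - wss(clusters[i]) - wss(clusters[j])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(frozenset(frozenset(c) for c in clusters))
        heights.append(d)
    return partitions, heights


def scipy_partitions(Z, n):
    """Partition sequence implied by a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    clusters = set(members.values())
    partitions = []
    for m, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        clusters -= {members[int(a)], members[int(b)]}
        clusters.add(merged)
        members[n + m] = merged
        partitions.append(frozenset(clusters))
    return partitions


class TestStandardize:
    def test_two_rows_plus_minus(self):
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 0.0]})
        out = fs.standardize(df)
        assert np.allclose(np.abs(out.to_numpy()), 1 / np.sqrt(2))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        once = fs.standardize(df)
        twice = fs.standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = fs.standardize(df)
        assert list(out.columns) == ["a"]

    def test_heading_becomes_cos_sin(self):
        df = pd.DataFrame({"mean_heading_deg": [0.0, 90.0, 180.0],
                           "a": [1.0, 2.0, 3.0]})
        out = fs.standardize(df)
        assert {"heading_cos", "heading_sin"} <= set(out.columns)
        assert "mean_heading_deg" not in out.columns

    def test_column_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(2, 5, size=(10, 4)), columns=list("abcd"))
        out = fs.standardize(df)
        assert np.allclose(out.mean(), 0, atol=1e-9)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-9)


class TestWard:
    def test_toy_merge_order_matches_oracle(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        Z, heights = ward_cluster(X)
        ref_partitions, ref_heights = greedy_ward_oracle(X)
        assert scipy_partitions(Z, 4) == ref_partitions
        assert np.allclose(heights, ref_heights, atol=1e-10)
        # first two merges are the tight pairs {0,1} and {10,11}
        assert {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))} == \
            {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("seed", [0, 4])
    def test_random_data_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(9, 3))
        Z, heights = ward_cluster(X)
        ref_partitions, ref_heights = greedy_ward_oracle(X)
        assert scipy_partitions(Z, 9) == ref_partitions
        assert np.allclose(heights, ref_heights, atol=1e-9)

    def test_heights_monotone_and_total_inertia(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        _, heights = ward_cluster(X)
        assert (np.diff(heights) >= -1e-9).all()
        total_wss = float(((X - X.mean(axis=0)) ** 2).sum())
        assert np.sum(heights) == pytest.approx(total_wss, rel=1e-9)

    def test_identical_rows_merge_at_zero(self):
        X = np.ones((4, 2))
        _, heights = ward_cluster(X)
        assert np.allclose(heights, 0.0)

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, size=(10, 2)),
                       rng.normal(10, 1, size=(10, 2))])
        Z, heights = ward_cluster(X)
        labels = cut_labels(Z, 2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            ward_cluster(np.zeros((2, 2)))


class TestChooseK:
    def test_toy_selects_two(self):
        _, heights = ward_cluster(np.array([[0.0], [1.0], [10.0], [11.0]]))
        assert choose_k(heights) == 2

    def test_three_blobs_selects_three(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(c, 0.5, size=(8, 2)) for c in (0, 10, 20)])
        _, heights = ward_cluster(X)
        assert choose_k(heights) == 3

    def test_equally_spaced_returns_valid_k(self):
        X = np.arange(8.0).reshape(-1, 1)
        _, heights = ward_cluster(X)
        k = choose_k(heights)
        assert 2 <= k <= 7

    def test_row_permutation_relabels_only(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.5, size=(6, 2)),
                       rng.normal(8, 0.5, size=(6, 2))])
        perm = rng.permutation(len(X))
        Z1, _ = ward_cluster(X)
        Z2, _ = ward_cluster(X[perm])
        l1 = cut_labels(Z1, 2)
        l2 = np.empty(len(X), int)
        l2[perm] = cut_labels(Z2, 2)
        # same partition up to renaming
        mapping = {}
        for a, b in zip(l1, l2):
            mapping.setdefault(a, b)
            assert mapping[a] == b


class TestCompareClusters:
    def test_identical_response_null(self):
        labels = [1, 1, 1, 2, 2, 2]
        res = fs.compare_clusters(labels, [5.0] * 6, list("abcdef"))
        assert res["lr"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([1, 2], 10)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        res = fs.compare_clusters(labels, y, np.arange(20))
        assert res["p"] < 0.001

    def test_f_equals_t_squared_two_clusters(self):
        y = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])
        labels = np.array([1, 1, 1, 2, 2, 2])
        res = fs.compare_clusters(labels, y, np.arange(6))
        t = stats.ttest_ind(y[:3], y[3:], equal_var=True).statistic
        assert res["F"] == pytest.approx(t ** 2, abs=1e-9)

    def test_singleton_excluded_from_pairwise(self):
        labels = [1, 1, 1, 2, 2, 3]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 9.0]
        res = fs.compare_clusters(labels, y, list("abcdef"))
        pairs = {(p["a"], p["b"]) for p in res["pairwise"]}
        assert pairs == {(1, 2)}


class TestClusterProfiles:
    def test_planted_strategies_recovered(self):
        cfg = fs.SimConfig(seed=21, n_individuals=12, n_strategies=3,
                           trips_per_individual=(4, 5), simulate_tdr=False,
                           mean_trip_distance_km=5.0)
        deployments, _, _, _, truth = fs.simulate_population(cfg)
        trips = []
        for dep in deployments:
            for tr in fs.segment_trips(fs.speed_filter(dep)):
                trips.append(fs.trip_metrics(tr, cfg.colony))
        profiles = fs.build_profiles(trips, None, cfg.colony)
        cols = ["mean_heading_deg"] + [c for c in fs.cluster.DEFAULT_FEATURES
                                       if c in profiles]
        sol = fs.cluster_profiles(profiles[cols], k=3)
        got = pd.Series(sol.labels, index=profiles["individual_id"])
        want = truth.individuals.set_index("individual_id")["strategy"]
        # same partition: every true strategy maps to exactly one cluster
        tab = pd.crosstab(got, want.loc[got.index])
        assert (tab.gt(0).sum(axis=0) == 1).all()
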