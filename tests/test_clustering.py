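import itertools

import numpy as np
import pytest

from erpstates import (
    ERPMatrix,
    apply_segmentation,
    average_epochs,
    cos_theta,
    grand_grandmean,
    kmeans_topographies,
    merge_short_microstates,
    normalize_by_gfp,
    segment_microstates,
    simulate_dataset,
    sweep_k,
)


def make_erp(data):
    data = np.asarray(data, dtype=float)
    return ERPMatrix(
        data=data,
        time_ms=4.0 * np.arange(data.shape[1]),
        montage=tuple(f"ch{i}" for i in range(data.shape[0])),
    )


def brute_force_best_partition(points: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster sum of squares over all
    assignments of the points into k (possibly fewer) clusters."""
    n = points.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        ss = 0.0
        for j in range(k):
            mask = assign == j
            if mask.any():
                c = points[mask].mean(axis=0)
                ss += ((points[mask] - c) ** 2).sum()
        best = min(best, ss)
    return best


class TestKmeans:
    def test_perfectly_separable_alternating_pair(self, rng):
        a, b = rng.normal(size=(2, 6))
        data = np.stack([a, b, a, b, a, b]).T  # channels x timepoints
        model = kmeans_topographies(make_erp(data), k=2, n_restarts=10, seed=0)
        assert model.inner_distance_sum == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(sorted(map(tuple, model.centroids)),
                                   sorted(map(tuple, [a, b])), atol=1e-12)
        np.testing.assert_array_equal(model.labels, [1, 2, 1, 2, 1, 2])

    def test_k1_centroid_is_mean_and_inertia_total_variance(self, rng):
        data = rng.normal(size=(4, 9))
        model = kmeans_topographies(make_erp(data), k=1, n_restarts=3, seed=0)
        np.testing.assert_allclose(model.centroids[0], data.mean(axis=1), atol=1e-12)
        expected = ((data.T - data.mean(axis=1)) ** 2).sum()
        assert model.inner_distance_sum == pytest.approx(expected)

    def test_matches_exhaustive_partition_search(self, rng):
        # 8 timepoints, k = 2: compare with enumeration of all assignments
        points = np.concatenate([
            rng.normal(0, 1, size=(4, 3)), rng.normal(4, 1, size=(4, 3))
        ])
        model = kmeans_topographies(make_erp(points.T), k=2, n_restarts=50, seed=1)
        assert model.inner_distance_sum == pytest.approx(
            brute_force_best_partition(points, 2), rel=1e-9
        )

    def test_matches_sklearn_inertia(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        points = np.concatenate([
            rng.normal(-3, 1, size=(10, 5)),
            rng.normal(0, 1, size=(10, 5)),
            rng.normal(3, 1, size=(10, 5)),
        ])
        ours = kmeans_topographies(make_erp(points.T), k=3, n_restarts=50, seed=0)
        km = sklearn.KMeans(n_clusters=3, n_init=50, max_iter=100, random_state=0)
        km.fit(points)
        assert ours.inner_distance_sum == pytest.approx(km.inertia_, rel=1e-6)

    def test_k_larger_than_timepoints_fails(self, rng):
        with pytest.raises(ValueError, match="timepoints"):
            kmeans_topographies(make_erp(rng.normal(size=(3, 4))), k=5)

    def test_duplicate_points_exhaust_reseeds(self):
        # only 2 distinct topographies: k = 3 always converges with an
        # empty cluster, so the re-seed counter runs out explicitly
        data = np.array([[1.0, 1.0, -1.0, -1.0], [0.0, 0.0, 2.0, 2.0]])
        with pytest.raises(RuntimeError, match="empty clusters"):
            kmeans_topographies(make_erp(data), k=3, n_restarts=2, max_reseeds=5)

    def test_restart_robustness_across_seeds(self, small_manifest):
        sets = simulate_dataset(small_manifest)
        erps = [normalize_by_gfp(average_epochs(es)) for es in sets]
        ggm = grand_grandmean(erps)
        a = kmeans_topographies(ggm, k=4, n_restarts=50, seed=1)
        b = kmeans_topographies(ggm, k=4, n_restarts=50, seed=2)
        assert a.inner_distance_sum == pytest.approx(b.inner_distance_sum, abs=1e-6)


class TestSegmentation:
    def test_runs_become_microstates(self):
        seg = segment_microstates(np.array([1, 1, 2, 2, 1]), 4.0 * np.arange(5))
        assert [m.cluster_id for m in seg.microstates] == [1, 2, 1]
        assert [m.index for m in seg.microstates] == [1, 2, 3]
        assert seg.microstates[0].start_ms == 0.0
        assert seg.microstates[-1].end_ms == 20.0  # half-open

    def test_uniform_labels_span_window(self):
        seg = segment_microstates(np.full(10, 3), 4.0 * np.arange(10))
        assert len(seg) == 1
        assert seg.microstates[0].duration_ms == 40.0

    def test_matches_independent_run_length_encoder(self, rng):
        labels = rng.integers(1, 4, size=80)
        t = 4.0 * np.arange(80)
        seg = segment_microstates(labels, t)
        # hand-rolled RLE oracle
        runs, start = [], 0
        for i in range(1, 81):
            if i == 80 or labels[i] != labels[i - 1]:
                runs.append((start, i, int(labels[start])))
                start = i
        assert len(seg) == len(runs)
        for m, (s, e, lab) in zip(seg.microstates, runs):
            assert m.cluster_id == lab
            assert m.start_ms == t[s]
            assert m.end_ms == t[e - 1] + 4.0

    def test_durations_sum_to_window_length(self, rng):
        labels = rng.integers(1, 5, size=150)
        seg = segment_microstates(labels, 4.0 * np.arange(150))
        assert sum(seg.durations_ms()) == pytest.approx(600.0)

    def test_merge_short_runs_is_optional_floor(self):
        t = 4.0 * np.arange(12)
        labels = np.array([1] * 5 + [2] * 1 + [3] * 6)  # middle run 4 ms
        merged = merge_short_microstates(labels, t, min_duration_ms=20.0)
        seg = segment_microstates(merged, t)
        assert all(m.duration_ms >= 20.0 for m in seg.microstates)


class TestApplySegmentation:
    def test_matches_bruteforce_columnwise_means(self, rng):
        data = rng.normal(size=(6, 20))
        labels = np.repeat([1, 2, 1, 3], 5)
        erp = make_erp(data)
        seg = segment_microstates(labels, erp.time_ms)
        vecs = apply_segmentation(erp, seg)
        for i, m in enumerate(seg.microstates):
            idx = [
                j for j, tt in enumerate(erp.time_ms)
                if m.start_ms <= tt < m.end_ms
            ]
            np.testing.assert_allclose(vecs[i], data[:, idx].mean(axis=1), atol=1e-12)

    def test_single_timepoint_microstate_is_that_column(self, rng):
        data = rng.normal(size=(4, 3))
        erp = make_erp(data)
        seg = segment_microstates(np.array([1, 2, 1]), erp.time_ms)
        np.testing.assert_array_equal(apply_segmentation(erp, seg)[1], data[:, 1])

    def test_constant_erp_gives_identical_vectors(self):
        erp = make_erp(np.tile(np.arange(5.0)[:, None], (1, 8)))
        seg = segment_microstates(np.repeat([1, 2], 4), erp.time_ms)
        vecs = apply_segmentation(erp, seg)
        np.testing.assert_allclose(vecs[0], vecs[1], atol=1e-12)

    def test_window_mismatch_fails(self, rng):
        erp = make_erp(rng.normal(size=(4, 10)))
        seg = segment_microstates(np.repeat([1, 2], 4), 4.0 * np.arange(8))
        with pytest.raises(ValueError, match="window"):
            apply_segmentation(erp, seg)


class TestSweep:
    def test_elbow_flattens_at_true_template_count(self, noiseless_manifest, small_manifest):
        sets = simulate_dataset(small_manifest)
        ggm = grand_grandmean([normalize_by_gfp(average_epochs(es)) for es in sets])
        sweep = sweep_k(ggm, range(2, 9), n_restarts=20, seed=0)
        t = sweep.table.set_index("k")["inner_distance_sum"]
        # non-increasing in k, sharp drop until the true k = 4, flat after
        assert all(t[k + 1] <= t[k] + 1e-9 for k in range(2, 8))
        drop_to_true = t[2] - t[4]
        flat_after = t[4] - t[8]
        assert drop_to_true > 5 * flat_after
        assert sweep.suggest_k_elbow() in (3, 4)

    def test_single_k_gives_single_row(self, rng):
        erp = make_erp(rng.normal(size=(5, 12)))
        sweep = sweep_k(erp, [2], n_restarts=5, seed=0)
        assert list(sweep.table["k"]) == [2]


def test_noiseless_recovery_is_exact(noiseless_manifest):
    """With no noise and k = n_templates, clustering the grand-grandmean
    recovers the generating segment boundaries exactly and the centroids
    equal the templates up to sign."""
    man = noiseless_manifest
    sets = [es for es in simulate_dataset(man) if es.condition == "A"]
    ggm = grand_grandmean([normalize_by_gfp(average_epochs(es)) for es in sets])
    model = kmeans_topographies(ggm, k=4, n_restarts=20, seed=0)
    seg = segment_microstates(model.labels, ggm.time_ms)
    truth = man.timeline.segments
    assert [(m.start_ms, m.end_ms) for m in seg.microstates] == [
        (s0, s1) for s0, s1, _ in truth
    ]
    # recurring templates must map to recurring clusters
    tid_by_cluster = {}
    for m, (_, _, tid) in zip(seg.microstates, truth):
        tid_by_cluster.setdefault(m.cluster_id, tid)
        assert tid_by_cluster[m.cluster_id] == tid
    for m, (_, _, tid) in zip(seg.microstates, truth):
        c = cos_theta(model.centroids[m.cluster_id - 1], man.template_set[tid])
        assert abs(c) == pytest.approx(1.0, abs=1e-9)
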