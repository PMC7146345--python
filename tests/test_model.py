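import numpy as np
import pytest
from sklearn.cluster import DBSCAN

from racquetclust.model import (
    UNKNOWN,
    FitError,
    HybridClusteringModel,
    HybridClusteringResults,
    SubFeatureCenter,
    classify_segments,
    count_movements,
    greedy_min_signature,
    layer1_fit,
    layer2_fit,
    layer3_fit,
    layer4_fit,
    segment_triples,
)

from .oracles import brute_force_dbscan


class TestLayer1:
    def test_magnitude_ranked_encoding(self):
        X = np.array([[1.0], [1.0], [9.0], [9.0], [5.0]])
        l1 = layer1_fit(X, k1=3, seed=0)
        assert np.array_equal(l1.encode(X), [0, 0, 2, 2, 1])

    def test_values_below_smallest_center_rank_zero(self):
        X = np.arange(1, 11, dtype=float)[:, None]
        l1 = layer1_fit(X, k1=3, seed=0)
        assert l1.encode(np.array([[-100.0]]))[0] == 0
        assert l1.encode(np.array([[100.0]]))[0] == 2

    def test_centers_strictly_increasing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        l1 = layer1_fit(X, k1=12, seed=0)
        assert np.all(np.diff(l1.centers) > 0)


class TestLayer2:
    def test_most_frequent_pattern_gets_label_zero(self):
        stream = np.array([0, 0] * 6 + [9, 9] * 2)
        l2 = layer2_fit([stream], k2=2, seed=0)
        assert l2.apply(np.array([0, 0]))[0] == 0
        assert l2.apply(np.array([9, 9]))[0] == 1

    def test_equal_counts_tie_breaks_to_lower_original_label(self):
        stream = np.array([0, 0] * 4 + [9, 9] * 4)
        l2 = layer2_fit([stream], k2=2, seed=0)
        labels = {int(l2.apply(np.array([0, 0]))[0]), int(l2.apply(np.array([9, 9]))[0])}
        assert labels == {0, 1}
        # rerun is identical (deterministic tie rule)
        l2b = layer2_fit([stream], k2=2, seed=0)
        assert np.array_equal(l2.freq_rank, l2b.freq_rank)

    def test_single_repeating_pattern_caps_clusters(self):
        stream = np.array([3, 3] * 5)
        l2 = layer2_fit([stream], k2=2, seed=0)
        assert np.array_equal(l2.apply(stream), np.zeros(5, dtype=int))


class TestLayer3:
    def test_window_count(self):
        tri = segment_triples(np.arange(10))
        assert tri.shape == (4, 3)

    def test_constant_stream_single_center(self):
        centers = layer3_fit({7: [np.full(12, 5)]}, k3=3, seed=0)
        assert len(centers) == 1
        assert centers[0].stats == (5.0, 5.0, 5.0)
        assert centers[0].movement_set == 7

    def test_two_level_stream_brute_force(self):
        centers = layer3_fit({0: [np.array([0, 0, 0, 0, 5, 5, 5, 5])]}, k3=2, seed=0)
        stats = sorted(tuple(np.round(c.stats, 6)) for c in centers)
        # windows: (0,0,0), (5,0,2.5), (5,5,5); the mixed window is
        # equidistant, so either 2-partition is the brute-force optimum
        valid = [
            [(0.0, 0.0, 0.0), (5.0, 2.5, 3.75)],
            [(2.5, 0.0, 1.25), (5.0, 5.0, 5.0)],
        ]
        assert stats in valid

    def test_short_stream_rejected(self):
        with pytest.raises(FitError):
            layer3_fit({0: [np.array([1, 2])]}, k3=2, seed=0)

    def test_stats_ordering_invariant(self):
        with pytest.raises(ValueError):
            SubFeatureCenter(stats=(1.0, 2.0, 1.5), center_label=0, movement_set=0)


class TestLayer4:
    def test_tight_shared_cluster_removed_far_point_kept(self):
        centers = [
            SubFeatureCenter((0.0, 0.0, 0.0), 0, 0),
            SubFeatureCenter((0.1, 0.0, 0.0), 1, 0),
            SubFeatureCenter((10.0, 10.0, 10.0), 2, 0),
            SubFeatureCenter((0.2, 0.0, 0.0), 0, 1),
            SubFeatureCenter((20.0, 20.0, 20.0), 1, 1),
        ]
        out = layer4_fit(centers, eps=0.5, min_pts=2)
        # the tight ε-chain spans both sets -> common, dropped; the isolated
        # points are each set's exclusive candidates
        assert np.allclose(out[0], [[10.0, 10.0, 10.0]])
        assert np.allclose(out[1], [[20.0, 20.0, 20.0]])

    def test_movement_with_only_common_centers_fails(self):
        centers = [
            SubFeatureCenter((0.0, 0.0, 0.0), 0, 0),
            SubFeatureCenter((0.1, 0.0, 0.0), 1, 0),
            SubFeatureCenter((0.2, 0.0, 0.0), 0, 1),
            SubFeatureCenter((10.0, 10.0, 10.0), 1, 1),
        ]
        with pytest.raises(FitError, match="movement 0"):
            layer4_fit(centers, eps=0.5, min_pts=2)

    def test_single_set_cluster_is_exclusive(self):
        centers = [SubFeatureCenter((float(i) / 10, 0.0, 0.0), i, 3) for i in range(4)]
        out = layer4_fit(centers, eps=0.5, min_pts=1)
        assert len(out[3]) == 4

    def test_empty_input(self):
        assert layer4_fit([], eps=0.5, min_pts=2) == {}

    @pytest.mark.parametrize("seed", range(6))
    def test_dbscan_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(int(rng.integers(10, 51)), 3))
        eps = float(rng.uniform(0.3, 1.2))
        min_pts = int(rng.integers(1, 5))
        ours = DBSCAN(eps=eps, min_samples=min_pts).fit(X).labels_
        oracle = brute_force_dbscan(X, eps, min_pts)
        # same noise set and same partition of the non-noise points
        assert np.array_equal(ours == -1, oracle == -1)
        for lab in set(oracle[oracle >= 0]):
            members = oracle == lab
            assert len(set(ours[members])) == 1


class TestClassify:
    SIG = {0: np.array([[0.0, 0.0, 0.0]]), 1: np.array([[4.0, 4.0, 4.0]])}

    def test_exact_center_match(self):
        labels, raw, norm = classify_segments(np.array([[4.0, 4.0, 4.0]]), self.SIG)
        assert labels[0] == 1 and raw[0] == 0.0 and norm[0] == 0.0

    def test_far_segment_is_unknown(self):
        thr = {0: 1.0, 1: 1.0}
        labels, _, _ = classify_segments(np.array([[100.0, 100.0, 100.0]]), self.SIG, thr)
        assert labels[0] == UNKNOWN

    def test_tie_goes_to_lower_movement_id(self):
        labels, _, _ = classify_segments(np.array([[2.0, 2.0, 2.0]]), self.SIG)
        assert labels[0] == 0


class TestCounting:
    def test_run_length_counts(self):
        assert count_movements([1, 1, 1, 2, 2, 1, 1], min_run=2) == {1: 2, 2: 1}

    def test_all_unknown(self):
        assert count_movements([UNKNOWN] * 5, min_run=2) == {}

    def test_run_too_short(self):
        assert count_movements([3], min_run=2) == {}

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            count_movements([1, 1], min_run=0)


class TestGreedy:
    @staticmethod
    def _score_fn(segments):
        """Proportion criterion over two one-class segment sets."""
        def score(sig):
            diffs = []
            for mov, triples in segments:
                labels, _, _ = classify_segments(triples, sig)
                diffs.append(abs(np.mean(labels == mov) - 1.0))
            return 1.0 - float(np.mean(diffs))
        return score

    def test_single_candidate_kept(self):
        cands = {0: np.array([[0.0, 0.0, 0.0]]), 1: np.array([[5.0, 5.0, 5.0]])}
        segs = [(0, np.zeros((4, 3))), (1, np.full((4, 3), 5.0))]
        out = greedy_min_signature(cands, self._score_fn(segs), tol=0.0)
        assert len(out[0]) == 1 and len(out[1]) == 1

    def test_infinite_tolerance_returns_singletons(self):
        rng = np.random.default_rng(0)
        cands = {m: rng.normal(size=(4, 3)) + 10 * m for m in range(3)}
        segs = [(m, rng.normal(size=(6, 3)) + 10 * m) for m in range(3)]
        out = greedy_min_signature(cands, self._score_fn(segs), tol=np.inf)
        assert all(len(v) == 1 for v in out.values())

    def test_reaches_exhaustive_optimum(self):
        # movement 0 has a harmful candidate sitting on movement 1's data;
        # exhaustive search over all subsets shows dropping it is optimal,
        # and the greedy path reaches that optimum
        cands = {
            0: np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0], [0.5, 0.0, 0.0]]),
            1: np.array([[5.2, 5.0, 5.0]]),
        }
        segs = [(0, np.zeros((5, 3))), (1, np.full((5, 3), 5.0))]
        score = self._score_fn(segs)
        out = greedy_min_signature(cands, score, tol=0.0)

        from itertools import combinations
        best = -np.inf
        for r in range(1, 4):
            for keep in combinations(range(3), r):
                best = max(best, score({0: cands[0][list(keep)], 1: cands[1]}))
        assert score(out) == pytest.approx(best)
        assert not any(np.allclose(c, [5.0, 5.0, 5.0]) for c in out[0])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            greedy_min_signature({0: np.empty((0, 3))}, lambda s: 1.0)


class TestEndToEnd:
    def test_noise_free_training_set_fully_recovered(self, quiet_dataset):
        res = HybridClusteringModel(quiet_dataset).fit(seed=0)
        hits = sum(res.predict_instance(r.series) == r.class_id for r in quiet_dataset.instances)
        assert hits == quiet_dataset.n_instances

    def test_save_load_round_trip(self, fitted_small, small_dataset, tmp_path):
        p = tmp_path / "model.yaml"
        fitted_small.save(p)
        loaded = HybridClusteringResults.load(p)
        for rec in small_dataset.instances[::17]:
            a = fitted_small.predict(rec.series)
            b = loaded.predict(rec.series)
            assert np.array_equal(a.segment_labels, b.segment_labels)
            assert a.counts == b.counts
            assert np.allclose(a.distances, b.distances)

    def test_permutation_stability(self, small_dataset):
        recs = [(r.class_id, r.series) for r in small_dataset.instances]
        res_a = HybridClusteringModel(recs, config=None).fit(seed=0)
        rng = np.random.default_rng(5)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        res_b = HybridClusteringModel(shuffled, config=None).fit(seed=0)
        assert np.allclose(res_a.layer1.centers, res_b.layer1.centers)
        for m in res_a.signatures:
            sa = np.asarray(sorted(map(tuple, res_a.signatures[m].exclusive_centers)))
            sb = np.asarray(sorted(map(tuple, res_b.signatures[m].exclusive_centers)))
            assert np.allclose(sa, sb)

    def test_counts_on_continuous_set(self, fitted_small, small_dataset):
        mset = small_dataset.sets[10]
        pred = fitted_small.predict(mset.series)
        assert sum(pred.counts.values()) >= 1
        assert all(v >= 0 for v in pred.counts.values())
        assert pred.point_labels is not None and len(pred.point_labels) == len(mset.series)

    def test_summary_mentions_key_parameters(self, fitted_small):
        s = fitted_small.summary()
        assert "k1" in s and "threshold" in s and "movement" in s

    def test_too_short_recording_rejected(self, fitted_small, small_dataset):
        import dataclasses

        rec = small_dataset.instances[0].series
        short = dataclasses.replace(
            rec, t=rec.t[:20], ax=rec.ax[:20], ay=rec.ay[:20], az=rec.az[:20],
            gx=rec.gx[:20], gy=rec.gy[:20], gz=rec.gz[:20],
        )
        with pytest.raises(ValueError, match="too short"):
            fitted_small.transform(short)
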