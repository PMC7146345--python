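"""The four-layer hybrid clustering model, statsmodels-style.

:class:`HybridClusteringModel` is built from labelled training recordings
(synthetic or loaded from disk) plus a :class:`~racquetclust.config.RunConfig`;
``fit()`` returns a :class:`HybridClusteringResults` carrying every fitted
parameter, diagnostics, a ``summary()`` table, ``predict()`` and YAML
serialization.

Layer 1 projects each sliding window's four-stream maximum vector to one
scalar by PCA and K-means-quantizes the scalars into k1 levels, relabelled
in increasing center magnitude so the code is a rank.  Layer 2 K-means
clusters non-overlapping pairs of consecutive ranks into k2 sub-features,
relabelled by descending frequency.  Layer 3 segments each movement's
sub-feature label stream with a 4/2 window, summarizes each segment by
(max, min, mean) and K-means-compresses the triples into k3 per-movement
sub-feature centers.  Layer 4 runs DBSCAN over all centers: density
clusters spanning two or more movements are common sub-features and are
discarded; noise points and single-movement clusters are the movement's
exclusive candidates.  A top-down greedy elimination then shrinks the
candidates to a minimal signature set under the proportion-accuracy
criterion.  Classification assigns each segment triple to the movement of
the nearest signature center (normalized Euclidean distance), or UNKNOWN
when the raw distance exceeds the movement's threshold; repetition counts
come from run-length encoding of the segment labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .cluster import kmeans
from .config import RunConfig, default_config
from .features import (
    FeatureStreams,
    PcaProjection,
    WindowSpec,
    compute_feature_streams,
    fit_pca_1d,
    sliding_windows,
    window_max_vectors,
)
from .preprocess import FilterConfig
from .synth import Dataset, ImuSeries

UNKNOWN = -1

SCHEMA_VERSION = 1

# fixed per-layer seed offsets derived from the master seed
_SEED_OFFSETS = {"layer1": 11, "layer2": 23, "layer3": 37}


class FitError(RuntimeError):
    """A layer of the hybrid fit failed; the message names the layer."""


@dataclass
class SubFeatureCenter:
    """(max, min, mean) summary of a layer-3 window, tagged by movement set."""

    stats: tuple[float, float, float]
    center_label: int
    movement_set: int

    def __post_init__(self):
        mx, mn, mean = self.stats
        if not (mx >= mean >= mn):
            raise ValueError(f"stats must satisfy max >= mean >= min, got {self.stats}")


@dataclass
class MovementSignature:
    """A movement's minimal exclusive sub-feature centers + distance threshold."""

    movement_id: int
    exclusive_centers: np.ndarray  # (m, 3) stat triples
    distance_threshold: float


@dataclass
class Prediction:
    """Per-segment movement labels, per-sample expansion and repetition counts."""

    segment_labels: np.ndarray  # movement id or UNKNOWN per segment
    distances: np.ndarray  # normalized distance of the winning movement per segment
    counts: dict[int, int]
    point_labels: np.ndarray | None = None  # per-sample expansion, if a series length was given


# ---------------------------------------------------------------------------
# layer 1: PCA + magnitude-ranked K-means encoding


@dataclass
class Layer1:
    pca: PcaProjection
    centers: np.ndarray  # strictly increasing scalar centers
    feature_scale: np.ndarray  # per-stream std of the training pool

    def encode(self, vectors) -> np.ndarray:
        """Rank (0..k1-1) of the nearest sorted center for each window vector."""
        X = np.asarray(vectors, dtype=float) / self.feature_scale
        scalars = np.atleast_1d(self.pca.project(X))
        return _nearest_sorted(self.centers, scalars)


def _nearest_sorted(sorted_centers: np.ndarray, values: np.ndarray) -> np.ndarray:
    mid = (sorted_centers[1:] + sorted_centers[:-1]) / 2.0
    return np.searchsorted(mid, values)


def layer1_fit(feature_vectors, k1: int, seed: int) -> Layer1:
    """PCA to 1-D, K-means on the scalars, clusters relabelled by magnitude.

    The four magnitude streams live on very different scales (m/s² vs m vs
    degrees), so each column is divided by its pooled standard deviation
    before the PCA; otherwise the largest-scale stream alone would define
    the principal direction.  The pooled scalars are sorted before
    clustering so the fit is invariant to the order in which training
    instances are supplied.
    """
    X = np.asarray(feature_vectors, dtype=float)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    pca = fit_pca_1d(Xs)
    scalars = np.sort(pca.project(Xs))
    res = kmeans(scalars, k1, seed=seed)
    centers = np.sort(np.atleast_1d(res.centers))
    return Layer1(pca=pca, centers=centers, feature_scale=scale)


# ---------------------------------------------------------------------------
# layer 2: sub-feature decomposition of rank pairs, frequency-sorted


@dataclass
class Layer2:
    centers: np.ndarray  # (k, 2) pair centers, original K-means order
    freq_rank: np.ndarray  # original label -> frequency rank (0 = most frequent)

    def apply(self, rank_stream) -> np.ndarray:
        """Sub-feature label per non-overlapping pair of consecutive ranks."""
        pairs = _rank_pairs(np.asarray(rank_stream))
        if len(pairs) == 0:
            return np.empty(0, dtype=int)
        orig = np.argmin(cdist(pairs, self.centers), axis=1)
        return self.freq_rank[orig]


def _rank_pairs(stream: np.ndarray) -> np.ndarray:
    """Non-overlapping pairs of consecutive ranks, (n // 2, 2)."""
    n = (len(stream) // 2) * 2
    return np.asarray(stream, dtype=float)[:n].reshape(-1, 2)


def layer2_fit(rank_streams, k2: int, seed: int) -> Layer2:
    """K-means over pooled rank pairs, labels reindexed by descending frequency.

    Ties in frequency break toward the smaller original label.  If the
    pooled pairs hold fewer distinct values than k2 the cluster count is
    capped (the surplus clusters would only be re-seeded empty).
    """
    pairs = np.concatenate([_rank_pairs(np.asarray(s)) for s in rank_streams], axis=0)
    if len(pairs) == 0:
        raise FitError("layer2: no rank pairs to cluster")
    order = np.lexsort(pairs.T[::-1])  # canonical order: permutation-stable fit
    pooled = pairs[order]
    k_eff = min(k2, np.unique(pooled, axis=0).shape[0])
    res = kmeans(pooled, k_eff, seed=seed)
    counts = np.bincount(res.assignments, minlength=k_eff)
    by_freq = sorted(range(k_eff), key=lambda c: (-counts[c], c))
    freq_rank = np.empty(k_eff, dtype=int)
    for rank, orig in enumerate(by_freq):
        freq_rank[orig] = rank
    return Layer2(centers=np.atleast_2d(res.centers), freq_rank=freq_rank)


# ---------------------------------------------------------------------------
# layer 3: windowed (max, min, mean) triples, K-means per movement set


def segment_triples(label_stream, window: WindowSpec = WindowSpec(4, 2)) -> np.ndarray:
    """(n_segments, 3) of (max, min, mean) per 4/2 window of a label stream."""
    w = sliding_windows(np.asarray(label_stream, dtype=float), window)
    return np.column_stack([w.max(axis=1), w.min(axis=1), w.mean(axis=1)])


def layer3_fit(streams_by_set: dict[int, list], k3: int, seed: int,
               window: WindowSpec = WindowSpec(4, 2)) -> list[SubFeatureCenter]:
    """Per movement set: 4/2 windowing, stat triples, K-means compression.

    Streams shorter than one window are skipped; a set with no usable
    stream is an error.  Triples are pooled in canonical (lexicographic)
    order so the fit is permutation-stable.
    """
    centers: list[SubFeatureCenter] = []
    for set_id in sorted(streams_by_set):
        triples = []
        for s in streams_by_set[set_id]:
            if len(s) >= window.length:
                triples.append(segment_triples(s, window))
        if not triples:
            raise FitError(f"layer3: movement set {set_id} has no stream of length >= {window.length}")
        pooled = np.concatenate(triples, axis=0)
        pooled = pooled[np.lexsort(pooled.T[::-1])]
        k_eff = min(k3, np.unique(pooled, axis=0).shape[0])
        res = kmeans(pooled, k_eff, seed=seed + set_id)
        C = np.atleast_2d(res.centers)
        C = C[np.lexsort(C.T[::-1])]
        for j, c in enumerate(C):
            # numerical guard: means of valid triples satisfy max >= mean >= min
            mx, mn, mean = float(c[0]), float(c[1]), float(c[2])
            centers.append(SubFeatureCenter(stats=(mx, mn, mean), center_label=j, movement_set=set_id))
    return centers


# ---------------------------------------------------------------------------
# layer 4: DBSCAN common/exclusive separation


def layer4_fit(centers: list[SubFeatureCenter], eps: float, min_pts: int) -> dict[int, np.ndarray]:
    """Split sub-feature centers into per-movement exclusive candidate sets.

    DBSCAN over all stat triples (Euclidean): members of a density cluster
    spanning >= 2 movement sets are common sub-features and dropped; noise
    points and single-set clusters are exclusive to their movement.  A
    movement left with no exclusive candidate is a fit failure.
    """
    if not centers:
        return {}
    X = np.array([c.stats for c in centers], dtype=float)
    sets = np.array([c.movement_set for c in centers])
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(X).labels_
    exclusive: dict[int, list] = {int(s): [] for s in np.unique(sets)}
    for lab in np.unique(labels):
        members = labels == lab
        if lab == -1:
            for i in np.flatnonzero(members):
                exclusive[int(sets[i])].append(X[i])
        else:
            owner_sets = np.unique(sets[members])
            if len(owner_sets) == 1:
                for i in np.flatnonzero(members):
                    exclusive[int(sets[i])].append(X[i])
            # else: common sub-feature, discarded
    out = {}
    for s, pts in exclusive.items():
        if not pts:
            raise FitError(f"layer4: movement {s} retains no exclusive sub-feature center; "
                           "adjust dbscan_eps or k3")
        out[s] = np.asarray(pts)
    return out


# ---------------------------------------------------------------------------
# classification, greedy signature search, counting


def classify_segments(triples: np.ndarray, signatures: dict[int, np.ndarray],
                      thresholds: dict[int, float] | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-signature classification of (n, 3) segment triples.

    Returns (labels, raw_min_distances, normalized_distances).  Per
    segment the Euclidean distance to each movement's nearest signature
    center is computed and normalized by the maximum across movements;
    the minimum normalized distance wins (ties to the lowest movement
    id).  With thresholds given, a winner whose raw distance exceeds its
    movement's threshold becomes UNKNOWN.
    """
    movs = sorted(signatures)
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    per_mov = np.column_stack([cdist(triples, np.atleast_2d(signatures[m])).min(axis=1) for m in movs])
    denom = per_mov.max(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    norm = per_mov / denom
    win = np.argmin(per_mov, axis=1)  # same argmin as normalized; ties -> lowest id
    labels = np.array([movs[w] for w in win])
    raw = per_mov[np.arange(len(triples)), win]
    normd = norm[np.arange(len(triples)), win]
    if thresholds is not None:
        thr = np.array([thresholds[m] for m in labels])
        labels = np.where(raw > thr, UNKNOWN, labels)
    return labels, raw, normd


def count_movements(per_point_labels, min_run: int = 2) -> dict[int, int]:
    """Repetition counts by run-length encoding of a label sequence.

    Runs of at least ``min_run`` consecutive equal labels increment the
    movement's count; UNKNOWN runs are never counted.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    labels = np.asarray(per_point_labels)
    counts: dict[int, int] = {}
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if labels[i] != UNKNOWN and j - i >= min_run:
            counts[int(labels[i])] = counts.get(int(labels[i]), 0) + 1
        i = j
    return counts


def proportion_score_from_segments(segments_by_set, expected_by_set, signatures) -> float:
    """Proportion-accuracy criterion over training movement sets.

    For each set, the predicted proportion is the fraction of its segments
    classified as the set's movement; the score is one minus the mean
    absolute difference from the expected proportion.
    """
    diffs = []
    for (mov, triples), expected in zip(segments_by_set, expected_by_set):
        labels, _, _ = classify_segments(triples, signatures)
        predicted = float(np.mean(labels == mov)) if len(labels) else 0.0
        diffs.append(abs(predicted - expected))
    return 1.0 - float(np.mean(diffs))


def _greedy_indices(candidates_idx: dict[int, list[int]], score_fn, tol: float) -> dict[int, list[int]]:
    """Index-based backward elimination shared by all greedy entry points.

    ``score_fn`` maps {movement: [candidate indices]} to the criterion
    value.  Drops are scanned in (movement id, candidate position) order
    and the first maximum wins, so the search is deterministic.
    """
    current = {m: list(v) for m, v in candidates_idx.items()}
    best = score_fn(current)
    while True:
        options = []
        for m in sorted(current):
            if len(current[m]) <= 1:
                continue
            for pos in range(len(current[m])):
                trial = dict(current)
                trial[m] = current[m][:pos] + current[m][pos + 1:]
                options.append((score_fn(trial), m, pos, trial))
        if not options:
            break
        top = max(options, key=lambda o: o[0])  # first max wins: scan order is deterministic
        if top[0] >= best - tol:
            current = top[3]
            best = max(best, top[0])
        else:
            break
    return current


def greedy_min_signature(candidates: dict[int, np.ndarray], score_fn, tol: float = 0.01) -> dict[int, np.ndarray]:
    """Top-down (backward) greedy elimination of signature centers.

    Starting from all exclusive candidates, repeatedly drop the single
    center whose removal yields the highest criterion value, as long as
    that value stays within ``tol`` of the best value seen; every
    movement keeps at least one center.
    """
    if not candidates or any(len(v) == 0 for v in candidates.values()):
        raise ValueError("every movement needs a non-empty candidate set")
    arrs = {m: np.atleast_2d(np.array(v, dtype=float)) for m, v in candidates.items()}

    def _score_idx(idx):
        return score_fn({m: arrs[m][v] for m, v in idx.items()})

    kept = _greedy_indices({m: list(range(len(a))) for m, a in arrs.items()}, _score_idx, tol)
    return {m: arrs[m][v] for m, v in kept.items()}


# ---------------------------------------------------------------------------
# the statsmodels-style model / results pair


# sample span bookkeeping: a 10/5 window w covers samples [5w, 5w+10); a
# rank pair covers two consecutive windows; a 4/2 segment covers 4 pairs.
def _segment_sample_span(window: WindowSpec, seg_window: WindowSpec):
    """(stride, span) in raw samples of one layer-3 segment."""
    pair_stride = 2 * window.step
    stride = seg_window.step * pair_stride
    span = (seg_window.length - 1) * pair_stride + pair_stride + (window.length - window.step)
    return stride, span


class HybridClusteringModel:
    """Four-layer hybrid clustering model of labelled IMU recordings.

    Parameters
    ----------
    recordings : list of (movement_id, ImuSeries) | Dataset
        Training material.  A :class:`~racquetclust.synth.Dataset` uses its
        single-repetition instances as training units.
    config : RunConfig, optional
        Pipeline parameters (k1/k2/k3, DBSCAN eps/min_pts, windows,
        filter settings...); defaults to the shipped configuration.
    """

    def __init__(self, recordings, config: RunConfig | None = None):
        if isinstance(recordings, Dataset):
            recordings = [(r.class_id, r.series) for r in recordings.instances]
        if not recordings:
            raise ValueError("need at least one training recording")
        self.recordings = list(recordings)
        self.config = config or default_config()
        movs = {m for m, _ in self.recordings}
        if len(movs) < 1:
            raise ValueError("need at least one movement class")

    # -- helpers shared with Results ------------------------------------
    @staticmethod
    def _filter_config(cfg: RunConfig, rate: float) -> FilterConfig:
        return FilterConfig(alpha=cfg.preprocess.alpha, median_window=cfg.preprocess.median_window,
                            sample_period=1.0 / rate)

    def fit(self, seed: int | None = None) -> "HybridClusteringResults":
        """Run layers 1-4 and the greedy signature search."""
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        w1 = WindowSpec(cfg.features.window_l1.length, cfg.features.window_l1.step)
        w3 = WindowSpec(cfg.features.window_l3.length, cfg.features.window_l3.step)

        # feature streams and window max vectors per recording
        vec_per_rec = []
        for mov, series in self.recordings:
            streams = compute_feature_streams(series, self._filter_config(cfg, series.sample_rate),
                                              chunk_samples=cfg.features.chunk_samples)
            vec_per_rec.append((mov, window_max_vectors(streams, w1)))

        try:
            pooled = np.concatenate([v for _, v in vec_per_rec], axis=0)
            l1 = layer1_fit(pooled, cfg.model.k1, seed + _SEED_OFFSETS["layer1"])
        except (ValueError, AssertionError) as e:
            raise FitError(f"layer1: {e}") from e

        rank_streams = [(mov, l1.encode(v)) for mov, v in vec_per_rec]
        try:
            l2 = layer2_fit([r for _, r in rank_streams], cfg.model.k2, seed + _SEED_OFFSETS["layer2"])
        except (ValueError, AssertionError) as e:
            raise FitError(f"layer2: {e}") from e

        label_streams = [(mov, l2.apply(r)) for mov, r in rank_streams]
        by_set: dict[int, list] = {}
        for mov, s in label_streams:
            by_set.setdefault(mov, []).append(s)
        centers = layer3_fit(by_set, cfg.model.k3, seed + _SEED_OFFSETS["layer3"], window=w3)
        # a movement whose centers all fall into shared density clusters has
        # no exclusive candidate; shrinking eps splits the offending merges,
        # so relax it stepwise before giving up
        eps = cfg.model.dbscan_eps
        last_err = None
        for _ in range(4):
            try:
                candidates = layer4_fit(centers, eps, cfg.model.dbscan_min_pts)
                break
            except FitError as e:
                last_err = e
                eps /= 2.0
        else:
            raise last_err

        # training segments per set for the greedy criterion
        seg_by_set = []
        for mov, s in label_streams:
            if len(s) >= w3.length:
                seg_by_set.append((mov, segment_triples(s, w3)))
        expected = np.ones(len(seg_by_set))  # training sets are pure single-movement recordings

        # precompute segment-to-candidate distances once; the greedy criterion
        # is then a cheap reduction instead of a classify pass per trial drop
        movs = sorted(candidates)
        offsets = {}
        cols = []
        for m in movs:
            offsets[m] = len(cols)
            cols.extend(np.atleast_2d(candidates[m]))
        all_triples = np.concatenate([t for _, t in seg_by_set])
        seg_set_id = np.concatenate([np.full(len(t), i) for i, (_, t) in enumerate(seg_by_set)])
        set_mov = np.array([mov for mov, _ in seg_by_set])
        set_sizes = np.array([len(t) for _, t in seg_by_set], dtype=float)
        seg_mov = set_mov[seg_set_id]
        D = cdist(all_triples, np.asarray(cols))
        movs_arr = np.array(movs)

        def score_idx(idx):
            per = np.column_stack(
                [D[:, [offsets[m] + p for p in idx[m]]].min(axis=1) for m in movs]
            )
            labels = movs_arr[np.argmin(per, axis=1)]
            correct = np.bincount(seg_set_id, weights=(labels == seg_mov), minlength=len(seg_by_set))
            return 1.0 - float(np.mean(np.abs(correct / set_sizes - expected)))

        kept = _greedy_indices(
            {m: list(range(len(candidates[m]))) for m in movs}, score_idx, tol=cfg.model.greedy_tol
        )
        signatures = {m: np.atleast_2d(candidates[m])[kept[m]] for m in movs}
        train_score = score_idx(kept)

        # per-movement distance threshold: high percentile of own-class distances
        own_dists: dict[int, list] = {m: [] for m in signatures}
        for mov, triples in seg_by_set:
            d = cdist(triples, np.atleast_2d(signatures[mov])).min(axis=1)
            own_dists[mov].extend(d.tolist())
        pct = cfg.model.threshold_percentile
        thresholds = {}
        for m in signatures:
            d = np.asarray(own_dists[m])
            q = float(np.percentile(d, pct, method="higher")) if len(d) else 1.0
            # floor at half the gap to the nearest other movement: a segment
            # that close is not "unrelated" even if the own-class training
            # distances happen to be very concentrated
            inter = np.inf
            for m2 in signatures:
                if m2 != m:
                    inter = min(inter, float(cdist(np.atleast_2d(signatures[m]),
                                                   np.atleast_2d(signatures[m2])).min()))
            thresholds[m] = max(q, 0.5 * inter if np.isfinite(inter) else q, 1e-9)
        sig_objs = {m: MovementSignature(m, signatures[m], thresholds[m]) for m in signatures}

        return HybridClusteringResults(
            config=cfg, seed=seed, layer1=l1, layer2=l2,
            signatures=sig_objs, training_score=train_score,
            n_training_recordings=len(self.recordings),
        )


@dataclass
class HybridClusteringResults:
    """Fitted parameters of the four layers plus thresholds and diagnostics."""

    config: RunConfig
    seed: int
    layer1: Layer1
    layer2: Layer2
    signatures: dict[int, MovementSignature]
    training_score: float
    n_training_recordings: int = 0

    # -- prediction ------------------------------------------------------
    def _windows(self):
        f = self.config.features
        return (WindowSpec(f.window_l1.length, f.window_l1.step),
                WindowSpec(f.window_l3.length, f.window_l3.step))

    def transform(self, series: ImuSeries) -> np.ndarray:
        """Layer 1-3 transform of a recording: (n_segments, 3) stat triples."""
        w1, w3 = self._windows()
        fc = HybridClusteringModel._filter_config(self.config, series.sample_rate)
        streams = compute_feature_streams(series, fc,
                                          chunk_samples=self.config.features.chunk_samples)
        ranks = self.layer1.encode(window_max_vectors(streams, w1))
        labels = self.layer2.apply(ranks)
        if len(labels) < w3.length:
            raise ValueError(f"recording too short: {len(labels)} sub-feature points, "
                             f"need >= {w3.length}")
        return segment_triples(labels, w3)

    def predict(self, series: ImuSeries, min_run: int | None = None) -> Prediction:
        """Classify a recording segment by segment and count repetitions."""
        triples = self.transform(series)
        sig = {m: s.exclusive_centers for m, s in self.signatures.items()}
        thr = {m: s.distance_threshold for m, s in self.signatures.items()}
        labels, raw, norm = classify_segments(triples, sig, thr)
        min_run = self.config.model.min_run if min_run is None else min_run
        counts = count_movements(labels, min_run=min_run)
        w1, w3 = self._windows()
        stride, span = _segment_sample_span(w1, w3)
        point = np.full(len(series), UNKNOWN, dtype=int)
        for i, lab in enumerate(labels):
            point[i * stride: min((i + 1) * stride, len(point))] = lab
        if len(labels):
            point[len(labels) * stride:] = labels[-1]
        return Prediction(segment_labels=labels, distances=norm, counts=counts, point_labels=point)

    def predict_instance(self, series: ImuSeries) -> int:
        """Single movement label for a short recording: majority over segments."""
        p = self.predict(series, min_run=1)
        known = p.segment_labels[p.segment_labels != UNKNOWN]
        if len(known) == 0:
            return UNKNOWN
        vals, cnt = np.unique(known, return_counts=True)
        return int(vals[np.argmax(cnt)])

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config.model
        lines = [
            "Hybrid clustering model results",
            "=" * 47,
            f"{'training recordings':<28}{self.n_training_recordings:>12}",
            f"{'k1 (encode levels)':<28}{cfg.k1:>12}",
            f"{'k2 (sub-features)':<28}{len(self.layer2.freq_rank):>12}",
            f"{'k3 (centers/movement)':<28}{cfg.k3:>12}",
            f"{'DBSCAN eps / min_pts':<28}{cfg.dbscan_eps:>8.3g} /{cfg.dbscan_min_pts:>3}",
            f"{'PCA explained variance':<28}{self.layer1.pca.explained_variance:>12.4f}",
            f"{'training proportion score':<28}{self.training_score:>12.4f}",
            "-" * 47,
            f"{'movement':<12}{'signature centers':>20}{'threshold':>14}",
        ]
        for m in sorted(self.signatures):
            s = self.signatures[m]
            lines.append(f"{m:<12}{len(s.exclusive_centers):>20}{s.distance_threshold:>14.4f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Write the fitted model as a versioned YAML document."""
        doc = {
            "schema_version": SCHEMA_VERSION,
            "seed": int(self.seed),
            "training_score": float(self.training_score),
            "n_training_recordings": int(self.n_training_recordings),
            "config": self.config.to_dict(),
            "pca": {
                "mean_vector": self.layer1.pca.mean_vector.tolist(),
                "loading_vector": self.layer1.pca.loading_vector.tolist(),
                "explained_variance": float(self.layer1.pca.explained_variance),
            },
            "layer1_centers": self.layer1.centers.tolist(),
            "layer1_feature_scale": self.layer1.feature_scale.tolist(),
            "layer2": {
                "centers": self.layer2.centers.tolist(),
                "freq_rank": self.layer2.freq_rank.tolist(),
            },
            "signatures": [
                {
                    "movement_id": int(m),
                    "centers": s.exclusive_centers.tolist(),
                    "distance_threshold": float(s.distance_threshold),
                }
                for m, s in sorted(self.signatures.items())
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "HybridClusteringResults":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema_version {doc.get('schema_version')}")
        cfg = RunConfig.from_dict(doc["config"])
        l1 = Layer1(
            pca=PcaProjection(
                mean_vector=np.asarray(doc["pca"]["mean_vector"], dtype=float),
                loading_vector=np.asarray(doc["pca"]["loading_vector"], dtype=float),
                explained_variance=float(doc["pca"]["explained_variance"]),
            ),
            centers=np.asarray(doc["layer1_centers"], dtype=float),
            feature_scale=np.asarray(doc["layer1_feature_scale"], dtype=float),
        )
        l2 = Layer2(
            centers=np.asarray(doc["layer2"]["centers"], dtype=float),
            freq_rank=np.asarray(doc["layer2"]["freq_rank"], dtype=int),
        )
        sigs = {
            int(s["movement_id"]): MovementSignature(
                int(s["movement_id"]),
                np.asarray(s["centers"], dtype=float),
                float(s["distance_threshold"]),
            )
            for s in doc["signatures"]
        }
        return cls(config=cfg, seed=int(doc["seed"]), layer1=l1, layer2=l2, signatures=sigs,
                   training_score=float(doc["training_score"]),
                   n_training_recordings=int(doc.get("n_training_recordings", 0)))
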