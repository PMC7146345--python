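"""Signal-magnitude feature streams, windowing and 1-D PCA reduction.

Four per-sample streams summarize the filtered 6-axis signal in an
orientation-robust way:

* ASMV — L2 norm of the (filtered) acceleration vector, m/s²;
* VSMV — L2 norm of the velocity vector obtained by cumulative
  integration of the gravity-removed acceleration, m/s;
* DSMV — L2 norm of the doubly integrated displacement vector, m;
* θSMV — L2 norm of the complementary-fused angle vector, degrees.

Integration is rectangular (running sum × T), the MCU-friendly form, and
resets at each instance start so gravity residues cannot drift.  Streams
are segmented by a sliding window (length 10, step 5 samples by default)
and summarized by per-window maxima; 1-D PCA reduces each window's
four-stream maximum vector to a single scalar for the first clustering
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import FilterConfig, FusedSeries, hbl_fuse, median_filter
from .synth import ImuSeries

STREAM_NAMES = ("asmv", "vsmv", "dsmv", "theta_svm")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (length and step, in samples or points)."""

    length: int
    step: int

    def __post_init__(self):
        if not (self.length >= self.step >= 1):
            raise ValueError(f"need length >= step >= 1, got length={self.length}, step={self.step}")


@dataclass
class FeatureStreams:
    """The four per-sample magnitude streams of one recording."""

    asmv: np.ndarray
    vsmv: np.ndarray
    dsmv: np.ndarray
    theta_svm: np.ndarray

    def __post_init__(self):
        n = len(self.asmv)
        if any(len(s) != n for s in (self.vsmv, self.dsmv, self.theta_svm)):
            raise ValueError("feature streams must share one length")

    def __len__(self) -> int:
        return len(self.asmv)

    def stacked(self) -> np.ndarray:
        """(n, 4) array in STREAM_NAMES order."""
        return np.column_stack([self.asmv, self.vsmv, self.dsmv, self.theta_svm])


@dataclass
class PcaProjection:
    """First principal direction of a feature-vector collection.

    The loading vector has unit L2 norm with its largest-magnitude
    component made positive, so the projection sign is deterministic.
    """

    mean_vector: np.ndarray
    loading_vector: np.ndarray
    explained_variance: float

    def project(self, v) -> np.ndarray:
        """Scalar projection loading · (v - mean); v is (d,) or (n, d)."""
        v = np.asarray(v, dtype=float)
        return (v - self.mean_vector) @ self.loading_vector


def asmv(ax, ay, az) -> np.ndarray:
    """Acceleration signal magnitude vector: sqrt(ax² + ay² + az²)."""
    return np.sqrt(np.square(np.asarray(ax, float)) + np.square(np.asarray(ay, float))
                   + np.square(np.asarray(az, float)))


def _integrate(acc: np.ndarray, T: float) -> np.ndarray:
    """Rectangular cumulative integration per column: cumsum × T."""
    return np.cumsum(acc, axis=0) * T


def vsmv(acc: np.ndarray, T: float) -> np.ndarray:
    """Velocity magnitude per sample from gravity-removed acceleration (n, 3)."""
    v = _integrate(np.asarray(acc, float), T)
    return np.linalg.norm(v, axis=1)


def dsmv(acc: np.ndarray, T: float) -> np.ndarray:
    """Displacement magnitude per sample: double cumulative integration."""
    a = np.asarray(acc, float)
    d = _integrate(_integrate(a, T), T)
    return np.linalg.norm(d, axis=1)


def theta_svm(theta: np.ndarray) -> np.ndarray:
    """Angle magnitude per sample from fused angles (n, 3), degrees."""
    return np.linalg.norm(np.asarray(theta, float), axis=1)


def remove_gravity(acc: np.ndarray) -> np.ndarray:
    """Subtract the per-instance mean acceleration vector from each axis.

    Raw accelerations include the quasi-constant gravity component, whose
    integral diverges; per-instance detrending is the minimal correction
    and resets at every instance start.
    """
    acc = np.asarray(acc, float)
    return acc - acc.mean(axis=0, keepdims=True)


def _streams_one_chunk(series: ImuSeries, config: FilterConfig) -> FeatureStreams:
    w = config.median_window
    filt = ImuSeries(
        series.t,
        median_filter(series.ax, w), median_filter(series.ay, w), median_filter(series.az, w),
        median_filter(series.gx, w), median_filter(series.gy, w), median_filter(series.gz, w),
        sample_rate=series.sample_rate,
    )
    fused: FusedSeries = hbl_fuse(filt, config)
    lin = remove_gravity(fused.acc_hbl)
    T = config.sample_period
    return FeatureStreams(
        asmv=asmv(fused.acc_hbl[:, 0], fused.acc_hbl[:, 1], fused.acc_hbl[:, 2]),
        vsmv=vsmv(lin, T),
        dsmv=dsmv(lin, T),
        theta_svm=theta_svm(fused.theta),
    )


def compute_feature_streams(series: ImuSeries, config: FilterConfig | None = None,
                            chunk_samples: int | None = None) -> FeatureStreams:
    """Full preprocessing + feature pipeline for one recording.

    Median-filters each channel, runs the complementary filter, then
    computes ASMV on the fused gravity estimate, VSMV/DSMV on the
    gravity-removed fused acceleration, and θSMV on the fused angles.

    ``chunk_samples`` processes the recording in independent buffers of
    that many samples (gravity estimate, integrators and angle filter all
    restart per buffer).  This is how the wristband operates on a
    continuous stream and is essential on long multi-movement traces,
    where a single global gravity mean and an unreset integrator would
    drift without bound; the trailing short remainder is merged into the
    last full buffer.  ``None`` treats the recording as one buffer.
    """
    config = config or FilterConfig(sample_period=series.sample_period)
    n = len(series)
    if chunk_samples is None or n <= chunk_samples:
        return _streams_one_chunk(series, config)
    starts = list(range(0, n, chunk_samples))
    if n - starts[-1] < max(config.median_window, 2):
        starts.pop()  # merge a tiny tail into the previous buffer
    parts = []
    for i, s0 in enumerate(starts):
        s1 = starts[i + 1] if i + 1 < len(starts) else n
        chunk = ImuSeries(
            series.t[s0:s1] - series.t[s0],
            series.ax[s0:s1], series.ay[s0:s1], series.az[s0:s1],
            series.gx[s0:s1], series.gy[s0:s1], series.gz[s0:s1],
            sample_rate=series.sample_rate,
        )
        parts.append(_streams_one_chunk(chunk, config))
    return FeatureStreams(
        asmv=np.concatenate([p.asmv for p in parts]),
        vsmv=np.concatenate([p.vsmv for p in parts]),
        dsmv=np.concatenate([p.dsmv for p in parts]),
        theta_svm=np.concatenate([p.theta_svm for p in parts]),
    )


def sliding_windows(stream, spec: WindowSpec) -> np.ndarray:
    """Segment a sequence into windows starting at 0, step, 2·step, …

    Returns an (n_windows, length) array; the trailing partial window is
    discarded.  A stream shorter than one window is an error.
    """
    x = np.asarray(stream)
    n, L, S = len(x), spec.length, spec.step
    if n < L:
        raise ValueError(f"stream of length {n} is shorter than one window of length {L}")
    n_w = (n - L) // S + 1
    idx = np.arange(L)[None, :] + S * np.arange(n_w)[:, None]
    return x[idx]


def window_stats(window) -> tuple[float, float, float]:
    """(max, min, mean) of one non-empty window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("window must be non-empty")
    return float(w.max()), float(w.min()), float(w.mean())


def window_max_vectors(streams: FeatureStreams, window: WindowSpec) -> np.ndarray:
    """Per-window maxima of the four streams: (n_windows, 4).

    This is the first layer's input representation: each 10/5 window
    contributes the maximum of each magnitude stream.
    """
    mats = [sliding_windows(s, window).max(axis=1)
            for s in (streams.asmv, streams.vsmv, streams.dsmv, streams.theta_svm)]
    return np.column_stack(mats)


def assemble_buffer_vectors(
    streams: FeatureStreams,
    buffer_samples: int = 155,
    window: WindowSpec = WindowSpec(10, 5),
    buffer_step: int | None = None,
) -> np.ndarray:
    """Fixed-length buffer feature vectors.

    Splits the recording into buffers of ``buffer_samples`` (default 155,
    i.e. 3.1 s at 50 Hz), applies the 10/5 windowing inside each buffer
    and concatenates the per-window maxima of the four streams,
    stream-major.  With the defaults each buffer yields 30 windows and a
    120-dimensional vector.
    """
    step = buffer_samples if buffer_step is None else buffer_step
    bufs = sliding_windows(np.arange(len(streams)), WindowSpec(buffer_samples, step))
    stacked = streams.stacked()
    out = []
    for idx in bufs:
        seg = stacked[idx]
        maxima = [sliding_windows(seg[:, j], window).max(axis=1) for j in range(seg.shape[1])]
        out.append(np.concatenate(maxima))
    return np.asarray(out)


def fit_pca_1d(vectors) -> PcaProjection:
    """Leading principal direction of a collection of equal-length vectors."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors of equal dimension")
    if np.allclose(X, X[0]):
        raise ValueError("zero variance: all vectors are identical")
    p = PCA(n_components=1).fit(X)
    loading = p.components_[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    return PcaProjection(
        mean_vector=p.mean_.copy(),
        loading_vector=loading,
        explained_variance=float(p.explained_variance_ratio_[0]),
    )
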