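"""Sliding-window artifact scoring and segmentation.

A fitted cluster model scores the recording in a 1-s sliding window with a
step of 0.1 times the sampling rate: each window's covariance matrix is
standardized against the nearest cluster's distance statistics and mapped
through the standard normal CDF into an outlier score in [0, 1].  The
window scores, anchored at window centers, are interpolated to a per-sample
trace starting and ending at 0, smoothed with a moving average, cut into
segments at local minima, and every segment whose score stays above the
threshold for at least the minimum artifact duration (0.4 s, the clinical
floor for a markable artifact) is emitted as a detected artifact.

Note on direction: the score reported here rises with distance from the
clusters — it is the probability that the window is an outlier.  (A score
defined as the CDF of the standardized distance already increases with
distance; complementing it would invert the intended direction.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .cluster import RiemannianPotatoes
from .preprocessing import Recording, epoch_covariance, lowpass_filter, split_epochs

__all__ = [
    "ScoreTrace",
    "ArtifactSegment",
    "window_scores",
    "build_trace",
    "smooth_trace",
    "segment_and_threshold",
    "detect",
    "ArtifactDetector",
]


@dataclass
class ScoreTrace:
    """Per-sample outlier probability aligned to the recording time base."""

    p_outlier: np.ndarray
    fs: float
    window_s: float = 1.0
    step_samples: int = 1

    def __post_init__(self):
        self.p_outlier = np.asarray(self.p_outlier, dtype=float)


@dataclass
class ArtifactSegment:
    """Half-open interval [start_s, end_s) flagged as artifact."""

    start_s: float
    end_s: float
    peak_score: float = float("nan")
    source: str = "detector"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def window_scores(
    rec: Recording,
    model: RiemannianPotatoes,
    window_s: float = 1.0,
    step_fraction: float = 0.1,
    shrinkage: float = 0.0,
) -> list[tuple[int, float]]:
    """Score sliding windows; returns (center_sample, p_outlier) pairs."""
    w = int(round(window_s * rec.fs))
    if w <= rec.n_channels and shrinkage == 0.0:
        raise ValueError("window too short for a full-rank covariance")
    step = int(round(step_fraction * rec.fs))
    if step < 1:
        raise ValueError("step must be at least one sample")
    if rec.n_samples < w:
        raise ValueError("recording shorter than one window")
    starts = np.arange(0, rec.n_samples - w + 1, step)
    covs = np.stack(
        [epoch_covariance(rec.signals[:, s : s + w], shrinkage) for s in starts]
    )
    p = model.score_samples(covs)
    centers = starts + w // 2
    return list(zip(centers.tolist(), p.tolist()))


def build_trace(
    scores: list[tuple[int, float]],
    rec_length: int,
    fs: float,
    window_s: float = 1.0,
    step_samples: int = 1,
) -> ScoreTrace:
    """Linear interpolation of window-center anchors to a per-sample trace.

    Zero anchors are added at the first and last sample (the scoring starts
    and ends with 0) and values are clipped to [0, 1].
    """
    if not scores:
        raise ValueError("no window scores to interpolate")
    centers = np.asarray([c for c, _ in scores], dtype=float)
    values = np.asarray([v for _, v in scores], dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")
    if centers[0] > 0:
        centers = np.concatenate(([0.0], centers))
        values = np.concatenate(([0.0], values))
    else:
        values[0] = 0.0
    last = rec_length - 1
    if centers[-1] < last:
        centers = np.concatenate((centers, [float(last)]))
        values = np.concatenate((values, [0.0]))
    else:
        values[-1] = 0.0
    trace = np.interp(np.arange(rec_length, dtype=float), centers, values)
    return ScoreTrace(
        p_outlier=np.clip(trace, 0.0, 1.0),
        fs=fs,
        window_s=window_s,
        step_samples=step_samples,
    )


def smooth_trace(trace: ScoreTrace, window_s: float = 0.5) -> ScoreTrace:
    """Centered moving average with edge-truncated averaging."""
    if window_s <= 0:
        raise ValueError("smoothing window must be positive")
    w = max(int(round(window_s * trace.fs)), 1)
    kernel = np.ones(w)
    num = np.convolve(trace.p_outlier, kernel, mode="same")
    den = np.convolve(np.ones_like(trace.p_outlier), kernel, mode="same")
    return ScoreTrace(
        p_outlier=num / den,
        fs=trace.fs,
        window_s=trace.window_s,
        step_samples=trace.step_samples,
    )


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Strict local minima over a 3-sample neighborhood; a flat plateau
    flanked by higher values counts once, at its center."""
    n = x.size
    minima = []
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                minima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(minima, dtype=int)


def segment_and_threshold(
    trace: ScoreTrace,
    threshold: float = 0.95,
    min_duration_s: float = 0.4,
) -> list[ArtifactSegment]:
    """Cut the trace at local minima and keep supra-threshold runs.

    Segment boundaries are the strict local minima of the smoothed trace
    plus the recording ends.  A segment is emitted as an artifact iff its
    samples above ``threshold`` span at least ``min_duration_s``; the
    emitted interval is that supra-threshold run.  Emitted runs separated
    by less than one scoring step are merged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    x = trace.p_outlier
    fs = trace.fs
    # ceil: an emitted run must last AT LEAST min_duration_s in seconds,
    # so the sample count is rounded up when min_duration_s*fs is fractional
    min_samples = int(np.ceil(min_duration_s * fs - 1e-9))
    bounds = np.concatenate(([0], _local_minima(x), [x.size]))
    bounds = np.unique(bounds)

    raw: list[tuple[int, int, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        above = np.flatnonzero(x[a:b] > threshold)
        if above.size == 0:
            continue
        run_start, run_stop = a + above[0], a + above[-1] + 1
        if above.size >= min_samples:
            raw.append((run_start, run_stop, float(x[run_start:run_stop].max())))

    merged: list[tuple[int, int, float]] = []
    for start, stop, peak in raw:
        if merged and start - merged[-1][1] < trace.step_samples:
            pstart, _, ppeak = merged[-1]
            merged[-1] = (pstart, stop, max(peak, ppeak))
        else:
            merged.append((start, stop, peak))
    return [
        ArtifactSegment(start_s=s / fs, end_s=e / fs, peak_score=p, source="detector")
        for s, e, p in merged
    ]


def detect(
    rec: Recording,
    model: RiemannianPotatoes,
    *,
    lowpass_hz: float = 30.0,
    window_s: float = 1.0,
    step_fraction: float = 0.1,
    threshold: float = 0.95,
    min_duration_s: float = 0.4,
    smooth_window_s: float = 0.5,
    shrinkage: float = 0.0,
    prefiltered: bool = False,
) -> tuple[ScoreTrace, list[ArtifactSegment]]:
    """Full scoring pipeline: filter -> window scores -> trace -> smooth ->
    segment.  Deterministic given inputs and configuration."""
    if rec.n_channels != model.n_channels_:
        raise ValueError(
            f"model was fitted on {model.n_channels_} channels, "
            f"recording has {rec.n_channels}"
        )
    filtered = rec if prefiltered else lowpass_filter(rec, lowpass_hz)
    step = int(round(step_fraction * rec.fs))
    scores = window_scores(filtered, model, window_s, step_fraction, shrinkage)
    trace = build_trace(scores, rec.n_samples, rec.fs, window_s, step)
    trace = smooth_trace(trace, smooth_window_s)
    segments = segment_and_threshold(trace, threshold, min_duration_s)
    return trace, segments


class ArtifactDetector(BaseEstimator):
    """End-to-end unsupervised artifact detector for multichannel EEG.

    ``fit`` low-pass filters the recording, cuts it into non-overlapping
    epochs, builds the cluster model of clean activity (with outlier
    pre-rejection and normality-based selection of the cluster count), and
    ``detect`` scores any recording against the fitted model.  In the
    usual fully-unsupervised mode both are run on the same recording.

    Parameters mirror the pipeline configuration: epoch length and scoring
    window (seconds), scoring step as a fraction of the sampling rate,
    low-pass cutoff (Hz), maximum cluster count, normality level alpha,
    outlier-probability threshold, minimum artifact duration (s), smoothing
    window (s), covariance shrinkage, and the RNG seed for k-means.
    """

    def __init__(
        self,
        epoch_length_s: float = 1.0,
        window_s: float = 1.0,
        step_fraction: float = 0.1,
        lowpass_hz: float = 30.0,
        k_max: int = 10,
        alpha: float = 0.05,
        threshold: float = 0.95,
        min_duration_s: float = 0.4,
        smooth_window_s: float = 0.5,
        shrinkage: float = 0.0,
        random_state: int | None = None,
    ):
        self.epoch_length_s = epoch_length_s
        self.window_s = window_s
        self.step_fraction = step_fraction
        self.lowpass_hz = lowpass_hz
        self.k_max = k_max
        self.alpha = alpha
        self.threshold = threshold
        self.min_duration_s = min_duration_s
        self.smooth_window_s = smooth_window_s
        self.shrinkage = shrinkage
        self.random_state = random_state

    def fit(self, rec: Recording, y=None):
        filtered = lowpass_filter(rec, self.lowpass_hz)
        epochs = split_epochs(filtered, self.epoch_length_s, shrinkage=self.shrinkage)
        self.model_ = RiemannianPotatoes(
            k_max=self.k_max,
            alpha=self.alpha,
            prereject=True,
            random_state=self.random_state,
        ).fit(epochs.covariances)
        self.n_training_epochs_ = len(epochs)
        return self

    def detect(self, rec: Recording) -> tuple[ScoreTrace, list[ArtifactSegment]]:
        return detect(
            rec,
            self.model_,
            lowpass_hz=self.lowpass_hz,
            window_s=self.window_s,
            step_fraction=self.step_fraction,
            threshold=self.threshold,
            min_duration_s=self.min_duration_s,
            smooth_window_s=self.smooth_window_s,
            shrinkage=self.shrinkage,
        )

    def fit_detect(self, rec: Recording):
        return self.fit(rec).detect(rec)
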