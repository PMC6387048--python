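"""Sliding-window scoring, trace construction, smoothing, segmentation."""

import numpy as np
import pytest
import scipy.stats

from rpotatoes.cluster import RiemannianPotatoes
from rpotatoes.detection import (
    ArtifactDetector,
    ScoreTrace,
    build_trace,
    detect,
    segment_and_threshold,
    smooth_trace,
    window_scores,
)
from rpotatoes.geometry import InvalidMatrixError
from rpotatoes.preprocessing import Recording, split_epochs

from .conftest import random_spd_stack


def make_trace(values, fs=100.0, step=10):
    return ScoreTrace(p_outlier=np.asarray(values, float), fs=fs, step_samples=step)


class TestBuildTrace:
    def test_single_midpoint_anchor_gives_triangle(self):
        trace = build_trace([(50, 1.0)], rec_length=101, fs=100.0)
        assert trace.p_outlier[0] == 0.0
        assert trace.p_outlier[100] == 0.0
        assert trace.p_outlier[50] == 1.0
        assert trace.p_outlier[25] == pytest.approx(0.5)
        assert trace.p_outlier[75] == pytest.approx(0.5)

    def test_constant_anchors_flat_interior(self):
        scores = [(c, 0.7) for c in range(10, 100, 10)]
        trace = build_trace(scores, rec_length=110, fs=100.0)
        np.testing.assert_allclose(trace.p_outlier[10:91], 0.7)
        assert trace.p_outlier[0] == 0.0
        assert trace.p_outlier[-1] == 0.0

    def test_midpoint_interpolation(self):
        trace = build_trace([(100, 0.2), (200, 0.8)], rec_length=301, fs=100.0)
        assert trace.p_outlier[150] == pytest.approx(0.5)

    def test_requires_increasing_centers(self):
        with pytest.raises(ValueError):
            build_trace([(50, 0.5), (50, 0.6)], rec_length=100, fs=100.0)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            build_trace([], rec_length=100, fs=100.0)


class TestSmoothTrace:
    def test_constant_unchanged(self):
        trace = make_trace(np.full(200, 0.4))
        out = smooth_trace(trace, window_s=0.5)
        np.testing.assert_allclose(out.p_outlier, 0.4)

    def test_impulse_becomes_plateau(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = smooth_trace(make_trace(x), window_s=0.5)  # w = 50 samples
        inner = out.p_outlier[90:110]
        np.testing.assert_allclose(inner, 1.0 / 50, rtol=1e-9)

    def test_never_increases_maximum(self, rng):
        for _ in range(20):
            x = rng.random(300)
            out = smooth_trace(make_trace(x), window_s=rng.uniform(0.05, 1.0))
            assert out.p_outlier.max() <= x.max() + 1e-12
            assert out.p_outlier.min() >= x.min() - 1e-12


class TestSegmentAndThreshold:
    def _hump(self, width_samples, height=1.0, fs=100.0):
        """Trace with one hump of the given supra-threshold width."""
        x = np.zeros(500)
        x[200 : 200 + width_samples] = height
        return make_trace(x, fs=fs)

    def test_supra_threshold_run_of_039s_is_dropped(self):
        segs = segment_and_threshold(self._hump(39), threshold=0.95, min_duration_s=0.4)
        assert segs == []

    def test_supra_threshold_run_of_050s_is_kept(self):
        segs = segment_and_threshold(self._hump(50), threshold=0.95, min_duration_s=0.4)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(0.5)
        assert segs[0].start_s == pytest.approx(2.0)

    def test_two_humps_split_by_local_minimum(self):
        x = np.zeros(1000)
        x[100:200] = 0.99
        x[250:350] = 0.99
        x[200:250] = 0.5  # dip below threshold between humps
        segs = segment_and_threshold(make_trace(x), threshold=0.95, min_duration_s=0.4)
        assert len(segs) == 2

    def test_threshold_monotonicity(self, rng):
        # total flagged duration never grows when the threshold is raised
        x = smooth_trace(make_trace(rng.random(2000)), 0.3).p_outlier
        durations = []
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            segs = segment_and_threshold(make_trace(x), threshold=thr, min_duration_s=0.1)
            durations.append(sum(s.duration_s for s in segs))
        assert all(a >= b - 1e-12 for a, b in zip(durations[:-1], durations[1:]))

    def test_segments_disjoint_sorted_and_long_enough(self, rng):
        x = smooth_trace(make_trace(rng.random(3000)), 0.2).p_outlier
        segs = segment_and_threshold(make_trace(x), threshold=0.6, min_duration_s=0.2)
        for s in segs:
            assert s.duration_s >= 0.2 - 1e-9
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_s <= b.start_s


@pytest.fixture(scope="module")
def fitted_model():
    r = np.random.default_rng(0)
    covs = random_spd_stack(r, 100, 3)
    return RiemannianPotatoes(k_max=1, prereject=False, random_state=0).fit(covs)


class TestWindowScores:

    def test_score_is_gaussian_cdf_of_standardized_distance(self, fitted_model):
        # a matrix whose standardized distance is z scores Phi(z); at the
        # distribution center the outlier score is exactly one half
        st = fitted_model.stats_[0]
        covs = random_spd_stack(np.random.default_rng(1), 50, 3)
        z = fitted_model.transform(covs)
        p = fitted_model.score_samples(covs)
        np.testing.assert_allclose(p, scipy.stats.norm.cdf(z), rtol=1e-12)
        idx = np.argmin(np.abs(z))
        if abs(z[idx]) < 0.05:
            assert p[idx] == pytest.approx(0.5, abs=0.03)

    def test_upper_tail_score(self):
        # standardized distance 1.6449 leaves 5% in the upper tail
        assert scipy.stats.norm.cdf(1.6449) == pytest.approx(0.95, abs=1e-4)

    def test_training_scores_uniform(self, small_synthetic):
        # scoring a model's own training epochs: standardized distances are
        # ~ standard normal, so Phi maps them to ~ Uniform(0,1)
        rec = small_synthetic.recording
        clean = ~small_synthetic.artifact_mask
        es = split_epochs(rec, 1.0)
        keep = np.array(
            [clean[s : s + int(rec.fs)].all() for s in es.start_indices]
        )
        model = RiemannianPotatoes(k_max=5, prereject=False, random_state=0).fit(
            es.covariances[keep]
        )
        p = model.score_samples(es.covariances[keep])
        assert scipy.stats.kstest(p, "uniform").pvalue > 0.01

    def test_window_step_and_centers(self, small_synthetic):
        rec = small_synthetic.recording
        es = split_epochs(rec, 1.0)
        model = RiemannianPotatoes(k_max=2, prereject=False, random_state=0).fit(
            es.covariances[:100]
        )
        scores = window_scores(rec, model, window_s=1.0, step_fraction=0.1)
        centers = np.array([c for c, _ in scores])
        assert np.all(np.diff(centers) == int(round(0.1 * rec.fs)))
        assert centers[0] == int(rec.fs) // 2

    def test_recording_shorter_than_window_rejected(self, rng):
        rec = Recording(signals=rng.standard_normal((3, 150)), fs=100.0)
        model = RiemannianPotatoes(k_max=1, prereject=False, random_state=0).fit(
            random_spd_stack(rng, 30, 3)
        )
        with pytest.raises(ValueError):
            window_scores(rec, model, window_s=2.0)


class TestDetectPipeline:
    def test_channel_mismatch_rejected(self, rng, small_synthetic):
        model = RiemannianPotatoes(k_max=1, prereject=False, random_state=0).fit(
            random_spd_stack(rng, 30, 3)
        )
        with pytest.raises(ValueError, match="channels"):
            detect(small_synthetic.recording, model)

    def test_zero_variance_recording_propagates_invalid_matrix(self, rng):
        model = RiemannianPotatoes(k_max=1, prereject=False, random_state=0).fit(
            random_spd_stack(rng, 30, 3)
        )
        rec = Recording(signals=np.zeros((3, 1000)), fs=100.0)
        with pytest.raises(InvalidMatrixError):
            detect(rec, model)

    def test_detector_deterministic(self, small_synthetic):
        rec = small_synthetic.recording
        det1 = ArtifactDetector(random_state=5).fit(rec)
        det2 = ArtifactDetector(random_state=5).fit(rec)
        t1, s1 = det1.detect(rec)
        t2, s2 = det2.detect(rec)
        np.testing.assert_array_equal(t1.p_outlier, t2.p_outlier)
        assert [(a.start_s, a.end_s) for a in s1] == [(b.start_s, b.end_s) for b in s2]

    def test_trace_covers_recording_in_unit_range(self, small_synthetic):
        rec = small_synthetic.recording
        det = ArtifactDetector(random_state=5).fit(rec)
        trace, segs = det.detect(rec)
        assert trace.p_outlier.size == rec.n_samples
        assert trace.p_outlier.min() >= 0.0
        assert trace.p_outlier.max() <= 1.0
        for s in segs:
            assert s.duration_s >= det.min_duration_s - 1e-9
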