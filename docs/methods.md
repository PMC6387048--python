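# Methods

## Model and assumptions

The detector treats a multichannel EEG recording as a sequence of
stationary 1-s epochs, each summarised by its uncentered spatial sample
covariance matrix C = XXᵀ/(m−1). The working assumptions are:

- clean activity occupies a small number of compact regions ("potatoes")
  on the SPD manifold, one or more per vigilance state, because spatial
  covariance patterns are stable within a state and differ across states;
- artifact epochs lie farther from every clean region than the clean
  regions lie from each other — artifacts are genuine outliers, not just
  a fourth regime;
- within one region, the log-distance of an epoch's covariance to the
  region's geometric mean is approximately Gaussian, so the region is
  fully described by its geometric mean centroid O, geometric mean
  distance μ and geometric SD σ.

All geometry uses the affine-invariant (Fisher) metric
δ(C₁,C₂) = ‖log(C₁^{-1/2} C₂ C₁^{-1/2})‖_F, invariant under channel
re-referencing and any non-singular linear mixing. The geometric mean of
a set is computed by the classical fixed-point iteration
M ← M^{1/2} exp[(1/k) Σ log(M^{-1/2}C_kM^{-1/2})] M^{1/2}, initialized at
the arithmetic mean. The iteration with a unit step is not contractive
for widely dispersed sets (it can oscillate when a candidate cluster
mixes well-separated regimes at high channel counts), so the step is
halved adaptively whenever the residual fails to decrease and relaxed
back toward 1 afterwards; the fixed point is unchanged.

The covariance estimator is uncentered by design: hardware high-pass
filtering keeps channel means near zero in clean data, and a voltage-jump
artifact shows up in the uncentered second moment. Mean removal and a
high-pass filter are available as options (off by default).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `epoch_length_s` | 1.0 | training epoch length (s); 1 s is the standard for covariance-based EEG analysis |
| `window_s` | 1.0 | scoring window length (s) |
| `step_fraction` | 0.1 | scoring step as a fraction of fs (0.1·fs samples) |
| `lowpass_hz` | 30 | zero-phase 4th-order Butterworth low-pass; keeps the sleep-relevant band |
| `k_max` | 10 | cap on the cluster count search |
| `alpha` | 0.05 | combined-normality level of the stopping rule |
| `threshold` | 0.95 | outlier probability above which samples count toward an artifact (≈ 1.645 geometric SDs) |
| `min_duration_s` | 0.4 | clinical minimum artifact duration |
| `smooth_window_s` | 0.5 | moving-average window on the score trace |
| `shrinkage` | 0.0 | covariance shrinkage toward (tr C/n)·I, for ill-conditioned high-density data |
| fuzzy `min_fraction` | 0.10 | border residual forgiven if ≥ this fraction of the artifact duration |
| fuzzy `max_lenient_s` | 1.5 | … and at most this long |

The geometric-mean iteration uses tolerance 1e-7 on the Frobenius norm of
the *mean* log-map (so the tolerance does not scale with the set size)
and at most 100 iterations. Eigenvalues below 1e-12 of the largest raise
an invalid-matrix error instead of being clipped; callers are pointed to
shrinkage.

## Cluster construction details

- **Pre-rejection** uses the arithmetic mean of the per-epoch mean
  distances d_i as threshold ("mean value" read as arithmetic; a
  geometric alternative would behave almost identically here since the
  d_i are narrowly distributed).
- **k-means** runs 4 seeded restarts per k (first deterministic
  farthest-point seeding, then distance-weighted sampling) and keeps the
  lowest inertia. A single probabilistic initialization proved unreliable
  at 19 channels, where the sampling spread of 1-s covariances is
  comparable to inter-regime separations and Lloyd iterations otherwise
  stick in partitions that split one regime and merge two others. Ties in
  the nearest-centroid assignment go to the lowest cluster index; an
  emptied cluster is reseeded with the point farthest from its centroid.
- **Stopping rule**: per cluster, member distances are standardized by
  that cluster's (μ, σ) and passed to D'Agostino's K² omnibus test;
  p-values are combined one-sidedly, Z = Σ Φ⁻¹(1−p_j)/√k. Clusters with
  fewer than 20 members make the configuration invalid (combined p = 0) —
  K² is unreliable below that size. Distances numerically equal to zero
  are floored at 1e-12 before taking logs. If no k reaches p > α the k
  with the largest p wins, ties toward smaller k.

## Scoring details

Window scores are anchored at window centers; the per-sample trace is the
linear interpolation of the anchors with zero anchors added at the first
and last sample, clipped to [0,1] and smoothed by an edge-truncated
moving average. Segment boundaries are strict local minima over a
3-sample neighborhood (plateau minima count once, at their center).
A segment is emitted iff its supra-threshold samples span at least
`min_duration_s`; the sample count is rounded *up* so every emitted
segment really lasts at least the minimum duration. Emitted runs closer
than one scoring step are merged.

The reported score is Φ(standardized distance), which *increases* with
distance from the nearest cluster — the natural orientation for an
outlier probability. (Composing the CDF with a complement, as a literal
reading of the belonging/outlier wording would suggest, inverts the
intended direction; the package reports the increasing orientation.)

## Evaluation details

Both labelings are rasterized at the recording's sampling rate with the
half-open convention (sample i covers [i/fs, (i+1)/fs)). A disagreeing
run touching an expert artifact border is forgiven (detector-only → TP,
expert-only → TN) when its duration is ≥ `min_fraction` of the adjacent
artifact's duration AND ≤ `max_lenient_s`. This literal rule penalizes
very small overshoots (a 0.3-s overshoot of a 10-s artifact fails the 10%
test); an alternative reading — forgiven when at most
max(10% · duration, 1.5 s) — is selectable via `lenient_rule="or"`.
A run covering an *entire* expert artifact is a complete miss, never a
border residual, and is never forgiven. Runs touching two artifacts use
the longer artifact's duration for the 10% test. Chance agreement uses
the standard two-rater marginal product
P_r = [(TP+FN)(TP+FP) + (FN+TN)(FP+TN)]/N², which keeps K invariant under
jointly swapping the positive and negative classes.

## The synthetic generator

`default_sleep_spec` emulates the statistical structure the detector
relies on, not the physiology of sleep EEG:

- **Three clean regimes** share a random eigenbasis and sit at the
  vertices of an equilateral triangle (side 6) in log-eigenvalue space;
  one difference direction is a spatial contrast (topography change), the
  other a uniform amplitude shift. The scale matches real stage
  contrasts: a 2–3× global amplitude change alone moves a covariance by
  √n·ln(4..9) ≈ 6–10 at 19 channels, and must exceed the ≈ 3 sampling
  spread of a 1-s SCM for stages to form distinct clusters at all.
- **Spectra** are shaped by low-pass filters at 25/15/8 Hz (wake-, REM-
  and deep-sleep-like) with a broadband noise floor (30/45/60% of
  variance, confined to the ≤30 Hz analysis band). The floor mirrors the
  EMG/amplifier background of real EEG; without it, a narrow-band regime
  has fewer temporal degrees of freedom per epoch than channels and its
  epoch covariances are near-singular. Rising floors keep the sampling
  spread comparable across regimes.
- **Regime schedule**: block-wise dwell times, whole seconds (so switches
  land on epoch boundaries and ground truth is regime-pure), drawn from
  unequal ranges per regime — the uneven stage prevalence of clinical
  recordings. The inequality also matters statistically: with exactly
  equal shares, a merged pair of regimes is equidistant from its centroid
  and its distance distribution is indistinguishable from normal, a blind
  spot of the stopping rule.
- **Artifacts** (≈ 8% of samples at the default rates): broadband bursts
  on all channels (6× RMS), frontal low-frequency blink lobes (10×),
  all-channel step offsets (6×), sustained single-channel noise (8×).
  Amplitudes are chosen so artifacts are farther from every clean cluster
  than the clusters are from each other — the regime the method is
  designed for. Events never overlap and keep 1 s clear of regime
  switches.

What the generator does **not** model: 1/f spectra, physiological
transients (spindles, K-complexes — known false-positive sources on real
data), within-stage drift, inter-channel delay structure. Passing tests
on this data therefore validate the geometry, clustering, scoring and
evaluation machinery — not clinical performance.

## Problem sizes used in tests and the acceptance script

Cluster-count recovery runs the 19-channel montage at 100 Hz with ≥ 200
epochs per regime (g·320 s, g ∈ {1,2,3}, 7 seeds each). The channel count
matters: the log-distance of an SCM to its Fréchet mean has an inherent
skew that scales like d^{-1/2} with the manifold dimension
d = n(n+1)/2, which the K² test reliably flags at a few hundred epochs
for n = 4 but not for n = 19. Detection recovery uses the default
19-channel, 250 Hz, 10-minute conditions over 5 seeds; the epoch-length
sweep (1/2/4 s) uses 2 seeds of the same conditions.

## Known limitations

- Stages or rare patterns not represented among the training clusters are
  flagged as artifacts (the method is unsupervised per recording).
- Artifacts confined to one channel move the covariance less than global
  ones; very localized events may score below threshold.
- With a single covariance regime and few channels, the normality rule
  can over-split when given many epochs, because K² then detects the
  finite-sampling skew of the distance distribution itself.
- The EDF writer targets plain EDF (16-bit, one-second records, uniform
  rate); EDF+ annotations are not written.
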