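# Methods

This note documents the models, parameter choices and numerical decisions
behind `breathsense`, and what the synthetic study does and does not show
about real recordings.

## Breathing model and reference protocol

Thorax motion is modelled as a sinusoid `s(t) = RE · sin(2π·RR/60·t)` in
normalized units (n.u., eupnea ≡ 1). The default protocol holds twelve
segments covering nine pattern classes:

| # | pattern | RR (bpm) | RE (n.u.) | augmentation RR range |
|---|---------|----------|-----------|----------------------|
| 1 | bradypnea | 5 | 1 | 5–10 |
| 2 | eupnea | 12 | 1 | 12–18 |
| 3 | hypopnea | 12 | 0.25 | 12–18 |
| 4 | hyperpnea | 10 | 2.5 | 12–18 |
| 5 | tachypnea | 35 | 1 | 20–35 |
| 6 | eupnea | 15 | 1 | 12–25 |
| 7 | Kussmaul | 30 | 2.5 | 20–35 |
| 8 | Cheyne–Stokes | 20 (active) | 0–4.5 | 12–25 |
| 9 | tachypnea | 35 | 0.25 | 20–35 |
| 10 | Biot's | 15 (active) | 1 | 12–25 |
| 11 | Biot's | 10 (active) | 2.5 | 12–25 |
| 12 | apnea | 0 | 0 | — |

Constant segments last 60 s. Biot's segments interleave two 20 s bursts
with two 20 s apneas (80 s). Cheyne–Stokes emits two cycles of a 15 s
linear crescendo (`RE(t) = RE/15·t`) plus 20 s apnea (70 s; the cycle
count is configurable — the pattern's cyclic shape fixes the cycle, not
the count). Segments start at phase zero so peak counts are reproducible,
and ≥5 s zero-valued pauses separate segments. Sampling is 10 Hz
throughout, enough for three harmonics of rates up to 100 breaths/min.

For classes appearing twice with different printed ranges (eupnea), the
augmentation uses the class's first range so the per-class rate
distribution stays a single uniform.

## Synthetic subjects and videos

A simulated subject applies, in order: smooth per-segment time-warping
(local playback rate within ±`rr_jitter_frac`, endpoints pinned so labels
stay aligned), a Kussmaul-only effort deficit, a global effort gain, a
response lag, sinusoidal baseline wander, and white Gaussian noise.
Defaults (the study conditions): noise sd 0.05 n.u., 5 % rate jitter,
baseline 0.1 n.u. at 0.02 Hz, Kussmaul gain 0.6 (subjects cannot produce
the demanded Kussmaul effort — which is also why augmentation replaces
Kussmaul sections with compressed hyperpnea). Cohorts draw per-subject
effort gains log-uniform in [0.7, 1.5], lags uniform in [0, 1] s and
Kussmaul gains in [0.5, 0.8]. With all corruption parameters zero the
subject equals the reference bit-for-bit.

Rendered videos are 64×64 px, 8-bit-scale intensities, 10 fps. RGB mode
translates a textured chest patch vertically by `gain·s[k]` px (bilinear
subpixel shift, so displacement is linear in the signal); IRT mode renders
a warm silhouette (≈200) on a cold background (≈50) with cloth-wrinkle
texture on the chest and a nose box whose mean intensity is modulated in
antiphase with the signal. An optional "bump" (global horizontal shift at
one frame) exercises the motion gate. The renderer emulates geometry and
contrast only — no photometric realism, no thermal airflow physics.

## Video extraction

Corner selection uses the minimum-eigenvalue (Shi–Tomasi) response with a
minimum peak distance; textureless regions fail loudly. Tracking is an
inverse-compositional Lucas–Kanade tracker (15 px window, 2 pyramid
levels, ≤30 iterations); points are dropped when their window leaves the
frame, the structure tensor degenerates, or the residual exceeds 25
intensity units. Trajectories are mean-centered before the SVD (an
uncentered SVD would point at the mean offset, not the motion direction)
and projected onto the first right singular vector; the arbitrary SVD sign
is normalized so every column correlates positively with the ensemble
mean.

Thermal border extraction thresholds the first frame with Otsu's method
(integer-aligned histogram for integer frames, making the threshold match
an exhaustive between-class-variance search), keeps the largest connected
component, and places `n = 30` boxes of 25×25 px at equal arc-length
spacing along the contour (smaller boxes on the 64×64 test scenes). The
motion error `e_m[k] = ‖O_k − O_{k−1}‖₂` marks unusable frames; RoIs are
re-initialized 2 s after the latest mark. The threshold default of 5
applies to raw intensity units and must be rescaled for scenes with other
contrasts (the synthetic IRT scene uses 30). Box means use the full box,
not foreground-masked pixels.

## Fusion

Mean correlation `ρ_μ,i = Σ_j ρ_ji / n` (self-term included) scores each
column; zero-variance columns score −∞. The top five columns enter the
moving-window PCA: 30 s windows, hop one sample, each window mean-centered
(removing baseline), `s[k]` = projection of the centered current row onto
the first principal direction. Sign continuity: each coefficient column is
flipped so the sign of its column sum matches the previous (adjusted)
window's — ties at exactly zero break toward +1. The trailing `wl − 1`
samples reuse the last complete window's direction. The column-sum rule is
blind when the leading coefficients genuinely sum to ≈0 (loadings rotating
through the diagonal); this is inherent to the sign convention, rare in
practice, and visible in tests as the one scenario where alignment cannot
help. Constant windows produce zero samples flagged invalid.

## Dataset: normalization, alignment, augmentation

Eupnea normalization divides by the maximum of the amplitude-scaled
(2/N) FFT magnitude of the eupnea section, DC bin excluded (a baseline
offset is not a breathing amplitude). Alignment estimates all pairwise
delays by cross-correlation and solves the rank-deficient linear system
`d_ij = d_i − d_j` by least squares anchored at `d_0 = 0`; the pipeline
includes the reference as signal 0 so all subjects land on the reference
time base. Residual clock-rate errors can be recovered by a grid search
over resampling factors 0.9–1.1 (step 0.001, ±10 % oscillator drift);
matches with peak correlation < 0.3 are flagged unreliable.

Augmentation mixes random record pairs with uniform `p`, cuts one
occurrence of the target class, and time-scales it (Fourier resampling —
band-limited, amplitude-preserving) so the rate lands uniformly in the
class range. Kussmaul is sourced from hyperpnea compressed into
20–35 breaths/min. Default 1000 segments per class, seeded.

## Features

* **Smoothing**: Savitzky–Golay, 1.5 s window, order 5. Order 3 at this
  window attenuates 35 breaths/min by ~15 %, destroying the amplitude
  feature of fast patterns; order 5 keeps attenuation below 1 % while
  halving white-noise amplitude.
* **Peak track**: `find_peaks` with prominence ≥ 0.1 n.u. and spacing
  ≥ 1.5 s (one period at 40 breaths/min). The prominence floor is tied to
  the artifact stage's 0.05 n.u. amplitude-reliability threshold
  (amplitude = prominence/2): weaker peaks would only contribute features
  the correction deems unreliable, and at 10 Hz they are mostly smoothed
  noise. Peak times and heights get parabolic sub-sample refinement —
  integer-sample spacing would quantize 35 breaths/min by >1.5 bpm.
  Rate/amplitude/width are hold-resampled (last value held); samples
  before the second peak are invalid.
* **CWT ridge**: analytic Morlet (`cmor1.5-1.0`), 12 voices per octave
  over 2–60 breaths/min, `argmax` over an amplitude-calibrated magnitude
  (per-scale calibration against unit sinusoids, so a unit sine reads
  ~1 n.u.), with parabolic refinement across the geometric frequency grid.
  The signal is padded by odd reflection — plain reflection breaks the
  oscillation phase at the boundary and biases the ridge over the first
  and last ~5 s. Ridge amplitudes below 0.01 n.u. mark the rate invalid.
* **Artifact rules** (per track, in order): (1) rate steps > 5 breaths/min
  between adjacent valid samples are marked; two marks within 10 s
  invalidate the enclosed span. (2) Spans with amplitude < 0.05 n.u.
  survive only if ≥ 5 median-rate periods long, median rate
  > 5 breaths/min, and rate spread < 0.45 of the median. (3) Valid
  segments shorter than 10 s are invalidated. (4) Gaps shorter than 10 s
  are filled with the median of the last five valid values (marked
  `filled` and never re-evaluated — this makes the correction idempotent);
  longer gaps are zeroed. Invalid samples are zero.
* **Merge**: segments bounded by >5 breaths/min jumps in either track; if
  the tracks' median rates agree within 3 breaths/min their elementwise
  mean is used (single-source samples fall back to the valid track),
  otherwise the track without a jump in the trailing 10 s and with the
  higher mean rate wins; no candidate → invalid. Gaps ≤ 5 s are
  median-filled, the rest zeroed. 30 s centered moving variances of the
  merged rate and amplitude complete the feature set.

## Classification

Per-section medians of rate, amplitude and both variances are computed
over the *complete* section of the zero-filled tracks, so a section that
is mostly unreliable (apnea) collapses robustly to the zero vector;
sections with under half their samples valid are flagged. The classifier
is a one-vs-one SVM — linear kernel, C = 1, features standardized with
training-fold statistics — under seeded stratified 10-fold
cross-validation. The median features are largely axis-separable, which is
why the linear kernel suffices; RBF is available by argument. Pairwise
voting ties resolve by aggregate decision-function margin.

## Problem sizes and what the tests show

The test suite runs the study at its full default scale: 10 subjects,
1000 augmented segments per class (≈100 s on one CPU). Under these
conditions the cross-validated accuracy is ≈0.99 with Biot's/Cheyne–Stokes
as the most-confused pair — the complex patterns overlap in all four
features. Feature-recovery checks run each pattern noise-free in
isolation: constant patterns per sample; intermittent patterns on active
phases and interior breaths, because a burst's first breath has half the
prominence by construction and a crescendo's half-prominence amplitude
equals its envelope at mid-breath (a quarter period from the crest, on
whichever side holds the shallower trough), not at the crest.

What passing does **not** show: the synthetic renditions contain no
posture shifts, lighting changes, clothing variation, camera noise,
perspective or out-of-plane motion; subject deviations are stationary
Gaussian/warp processes rather than behavioral; and thermal contrast is
idealized. Real-data accuracy will be lower, with the same qualitative
structure (complex-pattern confusion dominating).

## Known limitations

* The KLT tracker updates its template every frame; over very long
  sequences drift can accumulate (mitigated here by short test videos and
  error gating).
* The moving-window PCA sign rule fails when coefficient column sums
  vanish; a direction-continuity rule (inner product with the previous
  direction) would be strictly stronger but would change the published
  sign convention.
* WFDB support covers format-16 records; annotations are stored as
  plain-text tables rather than binary annotation files.
* The low-amplitude artifact rule can preserve spectrally stable noise
  ridges during apnea; the complete-section median makes the classifier
  robust to them, but per-sample apnea features remain noisy.
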