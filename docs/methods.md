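# Methods

`handkin` implements a criterion-validity analysis for paired markerless
hand-tracking measurements: two devices record the same repeated
flexion–extension task, and the package quantifies how well their
PIP-equivalent joint-angle trajectories agree. This note records the models,
the numerical choices, and what the synthetic cohort does and does not
establish.

## Measurement model and angle computation

Each device emits per-frame 3D hand landmarks under a fixed schema
(21 landmarks for the monocular-camera family, 24 for the infrared binocular
family). The flexion angle at a joint B flanked by landmarks A and C is the
included angle of the segment vectors,

    angle = arccos( (AB · BC) / (|AB| |BC|) ),

so a straight finger scores 0° and flexion grows toward 90–100°. The arccos
argument is clipped to [−1, 1]; exact collinearity is therefore well defined
numerically even though it is a measure-zero ideal. The computation is
invariant under rigid motion and uniform scaling (verified to 1e-9°), which
is what permits comparing devices with unrelated coordinate frames and
units. Conditioning degrades near 0° and 180° as arccos flattens; errors
there are of order 1e-6° rather than 1e-9°, irrelevant at sensor noise
scales.

The infrared device family cannot observe more than 90° of finger flexion;
angles are clamped with `min(angle, rom_cap)` after conversion. The 24-landmark
ordering shipped in `handkin/data/infrared24.json` is a declared convention
(no canonical public ordering exists); users of other layouts load their own
schema JSON.

Frame-rate disparity (60 vs 30 fps) is resolved by plain decimation, keeping
every second frame from frame 0. No anti-alias prefilter is applied: hand
motion content sits far below the 15 Hz post-decimation Nyquist, and the
12 Hz low-pass runs immediately downstream.

## Denoising chain

Order: Butterworth low-pass → ensemble Kalman smoothing (with grid-search /
cross-validated hyperparameters) → misestimated-frame detection → repair.

**Low-pass.** 2nd-order Butterworth, cutoff 12 Hz (the marker-based motion
capture convention), applied zero-phase with `filtfilt`. The effective
magnitude response is therefore |H(f)|², and no cutoff correction is applied.

**State model.** Per-channel constant velocity: state (θ, θ̇) with unit-frame
transition F = [[1,1],[0,1]], scalar observation of θ with variance R (deg²),
and white-acceleration process noise Q entering through G = (0.5, 1)ᵀ
(deg²/frame⁴). This is the minimal model that tracks flexion–extension
dynamics; it trades a little fidelity at movement reversals for robustness
on noise-dominated recordings.

**Hyperparameters.** R and Q are chosen per trajectory by grid search with
5-fold interleaved cross-validation (every 5th frame withheld). The score is
the mean Gaussian one-step predictive negative log-likelihood at withheld
frames under the exact Kalman filter of the same linear-Gaussian model —
exact, deterministic, and cheap, whereas the ensemble pass is reserved for
the actual smoothing. Likelihood scoring is essential: squared-error scoring
is minimised by maximal smoothing whenever the underlying signal is slow, so
it cannot identify the measurement-noise scale; predictive likelihood
penalises both over- and under-confident forecasts and recovers R near σ²
on noise-dominated series (checked across seeded replicates in the test
suite).

Grids: R ∈ {0.01, 0.1, 1, 10, 100} deg² spans device noise from "nearly
clean" to several degrees of jitter. Q ∈ {0.001, …, 1000} must reach the
squared per-frame acceleration of the fastest expected movement: a 2 Hz,
~90° flexion cycle at 30 fps accelerates at ≈ 17 deg/frame², so ceilings
below ~300 deg²/frame⁴ force the smoother to misread fast stage-V/VI
movement as noise and flatten it. With the full grid the chain preserves
clean-trajectory mean angular velocity within ~1% at every severity stage
while still cutting no-motion noise by far more than half.

**Ensemble smoother.** Perturbed-observation ensemble Kalman filter
(ensemble size 100, default seed 0) followed by an ensemble
Rauch–Tung–Striebel backward pass using the sample cross-covariance between
the analysis ensemble at t and the forecast ensemble at t+1 (2×2 inversion
with a 1e-9-scaled ridge). All stochastic perturbations are recentred to
exact zero mean, so the ensemble mean of a constant input is reproduced
exactly and the whole pass is a pure function of the seed. For this linear
model the ensemble smoother converges to the exact Kalman smoother; the
ensemble formulation is retained because it generalises to non-linear
observation operators without code changes.

**Misestimated frames.** With dx[i] = |x[i] − x[i−1]|, frame i is flagged
when dx[i] strictly exceeds mean(dx) + 3·sd(dx) (population SD; a constant
series yields no flags). A single bad frame inflates two consecutive
differences; when bridging frame i−1 to i+1 already falls under the
threshold, only frame i is attributed. Under a Gaussian null this flags
≈ 0.7–0.9% of frames (3-SD folded-normal tail), and detection power is
monotone in spike amplitude. Flagged values are re-filled linearly between
the nearest retained neighbours (edge-value extension at boundaries), then a
cubic smoothing spline with GCV-chosen stiffness passes over the whole
series. Exactly constant filled series skip the spline (GCV is
ill-conditioned at zero variance).

**Noise metric.** MAD = mean |x − mean(x)|, in degrees, evaluated on the
analysis window. For Gaussian noise MAD = σ·√(2/π), which is how the
synthetic device noise is calibrated (σ = MAD·√(π/2)).

## Features and severity trends

The analysis window keeps 10 s ≤ t < 20 s — the middle of the movement
phase of the task (5 s hold, 20 s repeated flexion–extension, 15 s maximum
reach). Per subject-finger-device the package reports peak flexion (deg),
peak and mean angular speed (deg/s, central differences with one-sided
endpoints, magnitudes only), window MAD, and an angle histogram with 2° bins
over [0, ROM cap], left-closed right-open with the last bin closed at the
cap so clamp mass is counted once. Stage-level histograms are elementwise
sums over subjects. Severity trends use Spearman rank correlation between
the ordinal stage (I–VI → 1–6, midranked ties) and a feature; p-values are
two-sided and unadjusted. By default the correlation pools all fingers of a
device; per-finger restriction is a keyword away.

## Agreement statistics

**DTW.** Dynamic programming over the standard three-predecessor recursion
with absolute-difference cost, infinite borders, and d(0,0) = 0; ties in the
backtrack prefer the diagonal. Both series are divided by 90° (the common
observable ROM) before alignment and the raw distance is divided by the
warp-path length, giving a dimensionless per-step distance; the raw distance
is also reported. An exhaustive-enumeration oracle (branch-and-bound over
all monotone paths, M·N ≤ 64) guards the dynamic program in tests.

**CCC.** Lin's concordance on time-aligned pairs with population (1/n)
moments: CCC = 2s_xy / (s_x² + s_y² + (μ_x − μ_y)²) = r · C_b. For pairing,
both series are linearly resampled onto a common 30 fps grid over the shared
window; optionally pairs are taken along the DTW warp path instead (useful
when device latency is suspected, since warping absorbs pure phase shift).
Grades follow the conventional bands, closed contiguously: very good
(0.9, 1], acceptable (0.7, 0.9], moderate (0.5, 0.7], poor (0.3, 0.5], no
agreement [−1, 0.3].

Stage summaries report min, quartiles (linear interpolation between order
statistics), median, mean and max of DTW and CCC per stage group, with
stages I and II pooled for reporting (no voluntary movement) but stored
distinctly.

## Synthetic cohort

The generator emulates the validation-study conditions: 40 subjects with
stage counts 2/8/6/6/9/9 (I…VI), five fingers each, 35 s recordings, both
devices observing the same clean trajectory with independent noise.

Clean trajectory: θ(t) = baseline + A·(0.5 − 0.5·cos 2πft)^p during the
movement phase, constant elsewhere, with per-subject amplitude drawn from
the stage profile (truncated at 0). The sharpening exponent p ≥ 1 makes the
trace dwell near its extremes, producing the bimodal extension/flexion
histograms characteristic of real recordings; because better-recovered
movement snaps more crisply between full extension and full flexion, p
grows with stage (1.2/1.4/1.6/2.0 for III–VI), which makes extreme-angle
dwell — and hence histogram bimodality — increase across stages already on
the clean waveform. Mean angular speed 2Af is independent of p, so this
does not disturb the velocity calibration. Stage profiles: amplitude 0 at baseline 50° for stages I–II
(no voluntary movement), then amplitude (mean ± sd) 46 ± 18, 78 ± 10,
89 ± 2, 89 ± 3 at baseline 10° for III–VI, tracking reported stage-wise
peak flexion of the long fingers; tempos 0.30/0.70/1.30/2.10 Hz chosen so
clean mean angular speed rises from ~28 to ~374 deg/s across stages. Stage
V and VI amplitudes are set equal so amplitude is non-decreasing in stage;
VI differs by tempo and sharpness. These are calibration targets, not
reproduction claims.

Device models: monocular — 30 fps, noise MAD 2.46°, spike rate 0.002,
ROM 180°; infrared — 60 fps, noise MAD 1.42°, spike rate 0.004, ROM clamped
at 90°, optional latency (default 0, configurable ±3 frames to stress DTW).
Spikes are ±40° Bernoulli events. Noise is independent across devices; no
shared error component is modelled.

What the generator does **not** emulate: tremor and spasticity waveforms,
within-subject finger coupling, landmark-level occlusion artefacts (noise is
injected at angle level), temperature-dependent infrared dropout, or any
non-stationarity across the recording. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it assumes — not that
either physical device is valid on patients.

## Problem sizes and determinism

Default recordings are 35 s (1050 frames at 30 fps); the end-to-end cohort
analysis covers 40 subjects × 5 fingers × 2 devices = 400 channels.
Reduced-size cohorts (fewer subjects/fingers, 25 s recordings) are used
where only plumbing is under test. Every stochastic step (trajectory draws,
device noise, ensemble perturbations) descends from explicit seeds via
`numpy` `SeedSequence` spawning; reports are written with fixed float
formatting, and rerunning any configuration with the same seed is
byte-identical.

## Known limitations

* The constant-velocity state model under-tracks at movement reversals when
  Q is small; the CV-selected Q compensates but slightly under-smooths slow
  noisy segments of fast recordings.
* DTW normalisation (divide by 90°, per-step averaging) is a declared
  convention; published distances from other normalisations are not directly
  comparable.
* The misestimation rule's threshold uses the global dx distribution, so a
  recording that is half still, half fast can flag legitimate fast frames;
  windowed thresholds were not implemented.
* CCC between devices with different ROM caps is structurally below 1 even
  for noise-free recordings whenever the movement exceeds 90°, since the
  capped device saturates; this mirrors the physical measurement situation
  rather than a pipeline defect.
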