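# handkin

Criterion-validity analysis for paired markerless hand-tracking systems.

After a stroke, finger flexion–extension kinematics track motor recovery
(the six-level Brunnstrom Recovery Stage, BRS). Two families of markerless
trackers can measure them — a monocular-camera landmark estimator (21
landmarks, 30 fps, noisier) and an infrared binocular device (24 landmarks,
60 fps, cleaner but with finger range of motion capped at 90°). `handkin`
is for movement scientists and rehabilitation engineers who need to ask:
*do these two devices agree well enough that one can stand in for the
other?*

The package implements the full analysis pipeline:

1. **Kinematics** — per-finger PIP-equivalent joint angles from landmark
   triples, `θ = arccos(AB·BC / |AB||BC|)`, with the device ROM clamp and
   frame-rate harmonisation (60 → 30 fps decimation).
2. **Denoising** — zero-phase 2nd-order Butterworth (12 Hz cutoff), ensemble
   Kalman smoothing under a constant-velocity state model with grid-search /
   cross-validated noise hyperparameters, and misestimated-frame repair
   (flag |Δθ| > mean + 3 SD, linear re-fill, GCV smoothing spline).
3. **Features** — peak flexion, peak/mean angular velocity, MAD noise, 2°
   angle histograms over the 10–20 s analysis window; Spearman correlation
   of each feature with severity stage.
4. **Agreement** — per subject-finger dynamic time warping distance
   (normalised by the common 90° ROM and warp-path length) and Lin's
   concordance correlation coefficient
   `CCC = 2s_xy / (s_x² + s_y² + (μ_x − μ_y)²) = r·C_b`,
   graded on the conventional Fleiss bands (very good > 0.9 … no
   agreement ≤ 0.3).
5. **Synthetic cohorts** — severity-staged paired recordings with
   device-calibrated noise (MAD 2.46° vs 1.42°), misestimation spikes, the
   90° clamp and the 60/30 fps disparity, so the whole pipeline is testable
   without patient data.

## Worked example

Simulate a small severity-staged cohort (one subject per stage) and analyze
it in one command:

```sh
handkin demo --outdir demo_out --seed 42 --small
```

which prints (abridged):

```json
{
  "agreement": {
    "ccc_median": 0.990473395,
    "dtw_median": 0.007059928,
    "median_grade_stages_III_VI": "very good"
  },
  "correlations": {
    "monocular": {
      "mean_velocity_deg_s": {"rho": 0.959501566, "p": 6.1006e-17}
    }
  },
  "mad_summary": {
    "infrared":  {"raw": 1.531504441, "processed": 0.291281353},
    "monocular": {"raw": 2.526129091, "processed": 0.445185606}
  },
  "n_channels": 30,
  "n_subjects": 6
}
```

Reading the numbers: the raw no-motion noise of each simulated device (MAD
2.53° and 1.53°) is cut by the denoising chain to 0.45° and 0.29°; mean
angular velocity rises with severity stage (Spearman ρ = 0.96 across the 30
subject-finger channels per device); and between-device agreement on the
moving stages is high (median CCC 0.990, i.e. "very good"; median
normalised DTW distance 0.007). The full report bundle — per-channel
features, agreement rows with warp paths, stage histograms, MAD table and
box-plot summaries — lands in `demo_out/` as CSV/JSON.

The same analysis runs on real recordings via a manifest of angle-series
CSV files (`handkin analyze manifest.csv`), on landmark files through the
schema-aware readers, or pairwise on two files (`handkin compare a.csv
b.csv`).

## Library use

```python
import handkin as hk

spec = hk.SyntheticCohortSpec(seed=0)          # 40 subjects, 2/8/6/6/9/9
records = hk.generate_cohort(spec)
res = hk.preprocess_chain(records[0].device_a) # denoise one channel
result = hk.compare_subject(
    hk.analysis_window(res.series),
    hk.analysis_window(hk.preprocess_chain(records[0].device_b).series),
)
print(result.ccc, result.grade)
```

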