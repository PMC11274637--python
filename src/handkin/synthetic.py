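"""Synthetic severity-staged paired-device cohorts.

Real stroke-rehabilitation recordings of this kind are not publicly
deposited, so the generator emulates their statistical structure: each
subject repeats hand flexion-extension cycles whose amplitude and tempo
grow with motor-recovery stage (the six-level ordinal BRS scale), and each
recording is observed through two imperfect devices — a monocular-camera
tracker (30 fps, 180-degree observable ROM, noisier) and an infrared
binocular tracker (60 fps, ROM capped at 90 degrees, cleaner but prone to
dropped/misestimated frames).

The clean trajectory is a sharpened sinusoid

    theta(t) = baseline + A * (0.5 - 0.5 cos(2 pi f t))^p

during the movement phase (seconds 5-25 of a 35-second task: 5 s hold,
20 s repeated flexion-extension, then hold at maximum reach), constant
elsewhere.  The exponent p >= 1 makes the trace dwell near the extremes,
reproducing the bimodal angle histograms of real flexion-extension data.
Device observation adds Gaussian noise calibrated through the mean
absolute deviation (sigma = MAD * sqrt(pi/2)), sporadic misestimated-frame
spikes, an optional frame latency, and the ROM clamp.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import STAGES, JointAngleSeries, LandmarkSequence, write_angle_series
from .schemas import FINGERS, HandSchema


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class StageProfile:
    """Clean-trajectory parameters of one severity stage.

    ``amplitude_mean_deg``/``amplitude_sd_deg`` give the per-subject draw of
    the flexion amplitude A; ``cycle_freq_hz`` the flexion-extension tempo;
    ``baseline_deg`` the resting extension angle; ``waveform_sharpness`` the
    dwell exponent p (>= 1) controlling histogram bimodality.
    """

    stage: str
    amplitude_mean_deg: float
    amplitude_sd_deg: float
    cycle_freq_hz: float
    baseline_deg: float
    waveform_sharpness: float = 1.5

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise SyntheticError(f"stage must be one of {STAGES}")
        if self.amplitude_mean_deg < 0 or self.amplitude_sd_deg < 0:
            raise SyntheticError("amplitude must be non-negative")
        if self.cycle_freq_hz < 0:
            raise SyntheticError("cycle frequency must be non-negative")
        if self.waveform_sharpness < 1:
            raise SyntheticError("waveform sharpness must be >= 1")
        if self.stage in ("I", "II") and self.amplitude_mean_deg != 0:
            raise SyntheticError("stage I-II profiles model no voluntary movement: amplitude must be 0")


# Stage profiles: amplitudes track reported stage-wise peak flexion of the
# long fingers (resting posture ~50 deg for the no-movement group, peaks
# rising to ~99 deg by stage V-VI); tempos chosen so clean mean angular
# speed (= 2 A f, independent of sharpness) rises from ~28 deg/s at stage
# III to ~374 deg/s at stage VI; waveform sharpness grows with stage so
# extreme-angle dwell (histogram bimodality) does too.  Stages I-II have no
# voluntary movement.
DEFAULT_STAGE_PROFILES: Mapping[str, StageProfile] = {
    "I": StageProfile("I", 0.0, 0.0, 0.0, 50.0),
    "II": StageProfile("II", 0.0, 0.0, 0.0, 50.0),
    "III": StageProfile("III", 46.0, 18.0, 0.30, 10.0, waveform_sharpness=1.2),
    "IV": StageProfile("IV", 78.0, 10.0, 0.70, 10.0, waveform_sharpness=1.4),
    "V": StageProfile("V", 89.0, 2.0, 1.30, 10.0, waveform_sharpness=1.6),
    "VI": StageProfile("VI", 89.0, 3.0, 2.10, 10.0, waveform_sharpness=2.0),
}

MOVEMENT_START_S = 5.0
MOVEMENT_END_S = 25.0


@dataclass(frozen=True)
class DeviceModel:
    """Observation model of one tracking device.

    ``noise_mad_deg`` calibrates the additive Gaussian noise through the
    MAD identity ``sigma = MAD * sqrt(pi/2)``; ``spike_rate`` is the
    per-frame probability of a misestimated-frame spike of amplitude
    ``+-spike_amp_deg``; ``latency_frames`` shifts the trace to stress
    phase robustness of the downstream alignment.
    """

    name: str
    fps: float
    noise_mad_deg: float
    spike_rate: float = 0.0
    spike_amp_deg: float = 40.0
    rom_cap_deg: float = 180.0
    latency_frames: int = 0

    def __post_init__(self) -> None:
        if self.noise_mad_deg < 0:
            raise SyntheticError("noise MAD must be non-negative")
        if not 0 <= self.spike_rate < 0.05:
            raise SyntheticError("spike rate must lie in [0, 0.05)")
        if self.rom_cap_deg not in (90.0, 180.0):
            raise SyntheticError("rom_cap_deg must be 90 or 180")


# Device noise MADs match the raw-data noise reported for the two systems
# (2.46 deg monocular vs 1.42 deg infrared on no-motion recordings).
DEFAULT_DEVICE_A = DeviceModel(
    name="monocular", fps=30.0, noise_mad_deg=2.46, spike_rate=0.002, rom_cap_deg=180.0
)
DEFAULT_DEVICE_B = DeviceModel(
    name="infrared", fps=60.0, noise_mad_deg=1.42, spike_rate=0.004, rom_cap_deg=90.0
)

#: Cohort composition of the validation study being emulated.
DEFAULT_STAGE_COUNTS: Mapping[str, int] = {"I": 2, "II": 8, "III": 6, "IV": 6, "V": 9, "VI": 9}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Complete description of a generated paired cohort."""

    n_per_stage: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    duration_s: float = 35.0
    base_fps: float = 60.0
    device_a: DeviceModel = DEFAULT_DEVICE_A
    device_b: DeviceModel = DEFAULT_DEVICE_B
    stage_profiles: Mapping[str, StageProfile] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROFILES)
    )
    fingers: tuple[str, ...] = FINGERS
    seed: int = 0

    def __post_init__(self) -> None:
        for stage, n in self.n_per_stage.items():
            if stage not in STAGES:
                raise SyntheticError(f"unknown stage {stage!r}")
            if n < 0:
                raise SyntheticError("stage counts must be >= 0")
        if self.duration_s <= 0:
            raise SyntheticError("duration must be positive")


def generate_trajectory(
    profile: StageProfile,
    duration_s: float,
    fps: float,
    seed: int,
    *,
    finger: str = "middle",
    subject_id: str = "synthetic",
    amplitude_deg: float | None = None,
) -> JointAngleSeries:
    """Clean (noise-free) angle trajectory for one subject-finger.

    The flexion amplitude is drawn once per call from the profile's
    normal law (truncated at 0) unless ``amplitude_deg`` pins it.  Before
    second 5 the trace rests at baseline; seconds 5-25 hold the repeated
    flexion-extension cycles; afterwards the trace holds its value at the
    end of the movement phase (the "maximum reach" hold).
    """
    if duration_s <= 0 or fps <= 0:
        raise SyntheticError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    if amplitude_deg is None:
        amplitude_deg = max(0.0, rng.normal(profile.amplitude_mean_deg, profile.amplitude_sd_deg))
    t = np.arange(int(round(duration_s * fps))) / fps
    theta = np.full(t.shape, profile.baseline_deg, dtype=float)
    moving = (t >= MOVEMENT_START_S) & (t < MOVEMENT_END_S)
    tm = t[moving] - MOVEMENT_START_S
    s = (0.5 - 0.5 * np.cos(2.0 * np.pi * profile.cycle_freq_hz * tm)) ** profile.waveform_sharpness
    theta[moving] += amplitude_deg * s
    after = t >= MOVEMENT_END_S
    if after.any() and moving.any():
        theta[after] = theta[moving][-1]
    return JointAngleSeries(
        finger=finger,
        fps=fps,
        angles=theta,
        rom_cap_deg=180.0,
        subject_id=subject_id,
        stage=profile.stage,
        device="clean",
    )


def apply_device_model(clean: JointAngleSeries, device: DeviceModel, seed: int) -> JointAngleSeries:
    """Observe a clean trajectory through a device.

    Steps, in order: linear resample to the device frame rate; latency
    shift (edge-held); additive Gaussian noise with
    ``sigma = noise_mad_deg * sqrt(pi/2)``; Bernoulli misestimation spikes
    of amplitude ``+-spike_amp_deg``; clamp to ``[0, rom_cap_deg]``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(len(clean) / clean.fps * device.fps))
    t_new = np.arange(n) / device.fps
    x = np.interp(t_new, clean.times, clean.angles)
    if device.latency_frames:
        k = device.latency_frames
        x = np.roll(x, k)
        if k > 0:
            x[:k] = x[k]
        else:
            x[k:] = x[k - 1]
    sigma = device.noise_mad_deg * np.sqrt(np.pi / 2.0)
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, size=n)
    if device.spike_rate > 0:
        hits = rng.random(n) < device.spike_rate
        signs = rng.choice((-1.0, 1.0), size=n)
        x = x + hits * signs * device.spike_amp_deg
    x = np.clip(x, 0.0, device.rom_cap_deg)
    return replace(
        clean,
        fps=device.fps,
        angles=x,
        rom_cap_deg=device.rom_cap_deg,
        device=device.name,
    )


@dataclass
class CohortRecord:
    """One generated subject-finger channel: clean trace + both devices."""

    subject_id: str
    stage: str
    finger: str
    clean: JointAngleSeries
    device_a: JointAngleSeries
    device_b: JointAngleSeries


def generate_cohort(spec: SyntheticCohortSpec) -> list[CohortRecord]:
    """Generate the full paired cohort described by ``spec``.

    Per subject and finger, one clean trajectory is drawn and observed
    through both device models with independent noise.  Child seeds are
    spawned deterministically from ``spec.seed``, so two calls with the
    same spec are identical.
    """
    records: list[CohortRecord] = []
    ss = np.random.SeedSequence(spec.seed)
    subject_no = 0
    for stage in STAGES:
        count = int(spec.n_per_stage.get(stage, 0))
        profile = spec.stage_profiles[stage]
        for _ in range(count):
            subject_no += 1
            subject_id = f"S{subject_no:02d}"
            for fi, finger in enumerate(spec.fingers):
                child = ss.spawn(1)[0]
                seeds = child.generate_state(3).tolist()
                clean = generate_trajectory(
                    profile,
                    spec.duration_s,
                    spec.base_fps,
                    int(seeds[0]) % (2**31),
                    finger=finger,
                    subject_id=subject_id,
                )
                dev_a = apply_device_model(clean, spec.device_a, int(seeds[1]) % (2**31))
                dev_b = apply_device_model(clean, spec.device_b, int(seeds[2]) % (2**31))
                records.append(
                    CohortRecord(
                        subject_id=subject_id,
                        stage=stage,
                        finger=finger,
                        clean=clean,
                        device_a=dev_a,
                        device_b=dev_b,
                    )
                )
    return records


def write_cohort(records: list[CohortRecord], outdir: str | Path) -> Path:
    """Write a cohort as angle-series files plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for label, series in (("a", rec.device_a), ("b", rec.device_b)):
            fname = f"{rec.subject_id}_{rec.finger}_{series.device}.csv"
            write_angle_series(series, outdir / fname)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "stage": rec.stage,
                    "finger": rec.finger,
                    "device": series.device,
                    "role": label,
                    "file": fname,
                }
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# landmark embedding (inverse of the angle computation, for round-trip tests)
# ---------------------------------------------------------------------------

def embed_angle(theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planar three-point chain whose included segment angle is ``theta``.

    Unit segments: A at the origin, B at (1, 0, 0), and C placed so the
    angle between A->B and B->C equals ``theta`` degrees.  Inverse of the
    angle computation, used for round-trip checks.
    """
    if not 0.0 <= theta <= 180.0:
        raise SyntheticError(f"theta must lie in [0, 180], got {theta}")
    rad = np.radians(theta)
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([1.0, 0.0, 0.0])
    c = b + np.array([np.cos(rad), np.sin(rad), 0.0])
    return a, b, c


def embed_angle_sequence(
    series: JointAngleSeries, schema: HandSchema
) -> LandmarkSequence:
    """Embed an angle series into a full landmark sequence under ``schema``.

    The series' finger triple carries the moving chain; all other landmarks
    are laid out on a fixed non-degenerate grid.  Round-tripping through
    the angle computation recovers the series (up to the schema ROM clamp).
    """
    n = len(series)
    coords = np.zeros((n, schema.n_landmarks, 3))
    # static scaffold: spread landmarks along y so no segment degenerates
    for i in range(schema.n_landmarks):
        coords[:, i, :] = (0.0, 2.0 + i, 1.0)
    ia, ib, ic = schema.joint_triples[series.finger]
    for k, theta in enumerate(series.angles):
        a, b, c = embed_angle(min(theta, 180.0))
        coords[k, ia] = a
        coords[k, ib] = b
        coords[k, ic] = c
    return LandmarkSequence(
        schema=schema,
        fps=series.fps,
        coords=coords,
        subject_id=series.subject_id,
        stage=series.stage,
    )
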