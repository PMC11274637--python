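"""Reading, writing and frame-rate harmonisation of landmark time series.

File dialect: the body is a UTF-8 comma-separated table with one header row
naming columns ``<landmark>_x|y|z`` and one row per frame; recording
metadata (schema name, fps, subject id, severity stage) lives in a JSON
sidecar with the same stem.  Per-finger joint-angle series reuse the same
dialect with one ``<finger>_deg`` column per finger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import FINGERS, HandSchema, SchemaError

#: Severity stages in clinical order; "unknown" is allowed for unlabelled data.
STAGES = ("I", "II", "III", "IV", "V", "VI")
STAGE_ORDINAL = {s: i + 1 for i, s in enumerate(STAGES)}


class LandmarkIOError(ValueError):
    """Raised for malformed landmark/angle files or invalid sequences."""


def _check_stage(stage: str) -> str:
    if stage not in STAGES and stage != "unknown":
        raise LandmarkIOError(f"stage must be one of {STAGES} or 'unknown', got {stage!r}")
    return stage


@dataclass
class LandmarkSequence:
    """An ordered series of hand-landmark frames from one recording.

    ``coords`` has shape ``(n_frames, n_landmarks, 3)``; frame ``i`` was
    captured at time ``i / fps`` seconds.
    """

    schema: HandSchema
    fps: float
    coords: np.ndarray
    subject_id: str = "unknown"
    stage: str = "unknown"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise LandmarkIOError(f"coords must have shape (frames, landmarks, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.schema.n_landmarks:
            raise LandmarkIOError(
                f"frame width {self.coords.shape[1]} != schema n_landmarks {self.schema.n_landmarks}"
            )
        if not np.isfinite(self.coords).all():
            raise LandmarkIOError("coordinates must be finite")
        if self.fps <= 0:
            raise LandmarkIOError(f"fps must be positive, got {self.fps}")
        _check_stage(self.stage)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class JointAngleSeries:
    """Per-finger PIP-equivalent flexion-angle trace in degrees.

    The working representation of the pipeline: one scalar angle per frame
    at a fixed frame rate, with the device's ROM cap carried along so that
    clamping and histogram binning know the observable range.
    """

    finger: str
    fps: float
    angles: np.ndarray
    rom_cap_deg: float = 180.0
    subject_id: str = "unknown"
    stage: str = "unknown"
    device: str = "unknown"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise LandmarkIOError("angles must be one-dimensional")
        if self.fps <= 0:
            raise LandmarkIOError(f"fps must be positive, got {self.fps}")
        if self.finger not in FINGERS:
            raise LandmarkIOError(f"finger must be one of {FINGERS}, got {self.finger!r}")
        _check_stage(self.stage)

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.angles)) / self.fps

    def with_angles(self, angles: np.ndarray) -> "JointAngleSeries":
        """Copy of this series with the angle samples replaced."""
        return replace(self, angles=np.asarray(angles, dtype=float))


# ---------------------------------------------------------------------------
# landmark CSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_landmark_sequence(seq: LandmarkSequence, path: str | Path) -> Path:
    """Write ``seq`` as a CSV body plus JSON metadata sidecar.

    Zero-frame sequences are refused: an empty body is indistinguishable
    from a truncated file.
    """
    if seq.n_frames == 0:
        raise LandmarkIOError("refusing to write a zero-frame sequence")
    path = Path(path)
    cols = [f"{nm}_{ax}" for nm in seq.schema.landmark_names for ax in "xyz"]
    flat = seq.coords.reshape(seq.n_frames, -1)
    df = pd.DataFrame(flat, columns=cols)
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "schema": seq.schema.name,
        "fps": seq.fps,
        "subject_id": seq.subject_id,
        "stage": seq.stage,
        "n_frames": seq.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_landmark_sequence(path: str | Path, schema: HandSchema) -> LandmarkSequence:
    """Read a landmark CSV (+ sidecar) under ``schema`` and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    expected = 3 * schema.n_landmarks
    if df.shape[1] != expected:
        raise SchemaError(
            f"{path.name}: {df.shape[1]} coordinate columns but schema "
            f"{schema.name!r} requires {expected} (3 x {schema.n_landmarks})"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise LandmarkIOError(f"{path.name}: non-numeric cell in body row {row}")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise LandmarkIOError(f"{path.name}: missing cell in body row {row}")
    coords = numeric.to_numpy(dtype=float).reshape(len(df), schema.n_landmarks, 3)

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fps = float(meta.get("fps", schema.native_fps))
    return LandmarkSequence(
        schema=schema,
        fps=fps,
        coords=coords,
        subject_id=str(meta.get("subject_id", "unknown")),
        stage=str(meta.get("stage", "unknown")),
    )


# ---------------------------------------------------------------------------
# angle-series CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_angle_series(series: JointAngleSeries, path: str | Path) -> Path:
    if len(series) == 0:
        raise LandmarkIOError("refusing to write an empty angle series")
    path = Path(path)
    df = pd.DataFrame({f"{series.finger}_deg": series.angles})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "finger": series.finger,
        "fps": series.fps,
        "rom_cap_deg": series.rom_cap_deg,
        "subject_id": series.subject_id,
        "stage": series.stage,
        "device": series.device,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_angle_series(path: str | Path) -> JointAngleSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path)
    col = f"{meta['finger']}_deg"
    if col not in df.columns:
        raise LandmarkIOError(f"{path.name}: expected column {col!r}")
    return JointAngleSeries(
        finger=meta["finger"],
        fps=float(meta["fps"]),
        angles=df[col].to_numpy(dtype=float),
        rom_cap_deg=float(meta.get("rom_cap_deg", 180.0)),
        subject_id=str(meta.get("subject_id", "unknown")),
        stage=str(meta.get("stage", "unknown")),
        device=str(meta.get("device", "unknown")),
    )


# ---------------------------------------------------------------------------
# frame-rate harmonisation
# ---------------------------------------------------------------------------

def _decimation_factor(fps: float, target_fps: float) -> int:
    factor = fps / target_fps
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise LandmarkIOError(f"fps {fps} is not an integer multiple of target {target_fps}")
    return int(round(factor))


def downsample(seq: LandmarkSequence, target_fps: float) -> LandmarkSequence:
    """Decimate to ``target_fps`` by keeping every k-th frame from frame 0.

    Plain decimation, no anti-alias prefilter: the denoising low-pass runs
    downstream at the harmonised rate, and hand-motion content lies far
    below the decimated Nyquist.
    """
    factor = _decimation_factor(seq.fps, target_fps)
    if factor == 1:
        return replace(seq, coords=seq.coords.copy())
    return replace(seq, fps=target_fps, coords=seq.coords[::factor].copy())


def downsample_angles(series: JointAngleSeries, target_fps: float) -> JointAngleSeries:
    """Decimate an angle series to ``target_fps`` (same rule as `downsample`)."""
    factor = _decimation_factor(series.fps, target_fps)
    if factor == 1:
        return series.with_angles(series.angles.copy())
    return replace(series, fps=target_fps, angles=series.angles[::factor].copy())
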