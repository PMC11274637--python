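"""Kinematic feature extraction over the analysis window.

Features per subject-finger-device: peak flexion (deg), peak and mean
angular speed (deg/s), MAD (deg), and a 2-degree-bin angle histogram over
[0, ROM cap].  The analysis window defaults to seconds 10-20 of the
recording — the middle of the repeated flexion-extension phase of the
measurement protocol.  Stage-pooled histograms and Spearman correlations
between severity stage and a feature summarise cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import STAGE_ORDINAL, STAGES, JointAngleSeries
from .kinematics import VelocitySeries
from .preprocess import mad as _mad

HISTOGRAM_BIN_DEG = 2.0


class FeatureError(ValueError):
    pass


def analysis_window(
    series: JointAngleSeries, start_s: float = 10.0, end_s: float = 20.0
) -> JointAngleSeries:
    """Restrict a series to frames with ``start_s <= t < end_s``."""
    duration = len(series) / series.fps
    if not (0 <= start_s < end_s <= duration + 1e-9):
        raise FeatureError(
            f"window [{start_s}, {end_s}) outside recording of {duration:.2f} s"
        )
    t = series.times
    keep = (t >= start_s) & (t < end_s)
    return series.with_angles(series.angles[keep])


def histogram_edges(rom_cap_deg: float) -> np.ndarray:
    """Bin edges [0, 2, 4, ...] up to the ROM cap.

    Bins are left-closed right-open except the last, which closes at the
    cap so that clamp mass sitting exactly on the cap is counted once.
    """
    return np.arange(0.0, rom_cap_deg + HISTOGRAM_BIN_DEG / 2, HISTOGRAM_BIN_DEG)


@dataclass
class KinematicFeatures:
    """Scalar kinematic summary of one subject-finger-device window."""

    subject_id: str
    stage: str
    finger: str
    device: str
    peak_flexion_deg: float
    peak_velocity_deg_s: float
    mean_velocity_deg_s: float
    mad_deg: float
    histogram: np.ndarray
    bin_edges: np.ndarray

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "stage": self.stage,
            "finger": self.finger,
            "device": self.device,
            "peak_flexion_deg": self.peak_flexion_deg,
            "peak_velocity_deg_s": self.peak_velocity_deg_s,
            "mean_velocity_deg_s": self.mean_velocity_deg_s,
            "mad_deg": self.mad_deg,
        }


FEATURE_NAMES = ("peak_flexion_deg", "peak_velocity_deg_s", "mean_velocity_deg_s", "mad_deg")


def extract_features(series: JointAngleSeries, velocity: VelocitySeries) -> KinematicFeatures:
    """Compute the per-window feature set from matched angle/velocity series."""
    if len(series) == 0:
        raise FeatureError("empty analysis window")
    if len(series) != len(velocity):
        raise FeatureError("angle and velocity series must share the window")
    edges = histogram_edges(series.rom_cap_deg)
    counts, _ = np.histogram(np.clip(series.angles, 0.0, series.rom_cap_deg), bins=edges)
    return KinematicFeatures(
        subject_id=series.subject_id,
        stage=series.stage,
        finger=series.finger,
        device=series.device,
        peak_flexion_deg=float(series.angles.max()),
        peak_velocity_deg_s=float(velocity.speed.max()),
        mean_velocity_deg_s=float(velocity.speed.mean()),
        mad_deg=_mad(series),
        histogram=counts,
        bin_edges=edges,
    )


class CohortFeatureTable:
    """Feature rows keyed by (subject, finger, device), one row per key."""

    def __init__(self, rows: Iterable[KinematicFeatures] = ()):
        self.rows: list[KinematicFeatures] = []
        self._keys: set[tuple[str, str, str]] = set()
        for row in rows:
            self.add(row)

    def add(self, row: KinematicFeatures) -> None:
        key = (row.subject_id, row.finger, row.device)
        if key in self._keys:
            raise FeatureError(f"duplicate feature row for {key}")
        if row.stage not in STAGES and row.stage != "unknown":
            raise FeatureError(f"invalid stage {row.stage!r}")
        self._keys.add(key)
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def select(self, *, stage=None, finger=None, device=None) -> list[KinematicFeatures]:
        out = self.rows
        if stage is not None:
            wanted = set(stage) if isinstance(stage, (list, tuple, set)) else {stage}
            out = [r for r in out if r.stage in wanted]
        if finger is not None:
            out = [r for r in out if r.finger == finger]
        if device is not None:
            out = [r for r in out if r.device == device]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.rows])


def stage_histogram(
    features: CohortFeatureTable, stage: str | Sequence[str], finger: str, device: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pool member histograms of one severity stage (elementwise sum).

    Returns ``(counts, bin_edges)``.  Stages may be given as a single label
    or a group (e.g. ``("I", "II")`` for the pooled no-movement group).
    """
    members = features.select(stage=stage, finger=finger, device=device)
    if not members:
        raise FeatureError(f"no subjects at stage {stage!r} for finger {finger!r}")
    edges = members[0].bin_edges
    for m in members[1:]:
        if len(m.bin_edges) != len(edges) or not np.allclose(m.bin_edges, edges):
            raise FeatureError("cannot pool histograms with differing bin edges")
    counts = np.sum([m.histogram for m in members], axis=0)
    return counts, edges


def stage_feature_correlation(
    features: CohortFeatureTable,
    feature_name: str,
    *,
    finger: str | None = None,
    device: str | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between severity stage and a feature.

    Stages map to ordinals I-VI -> 1-6; ties are midranked.  By default the
    correlation pools all fingers present (restrict with ``finger=``).
    Returns ``(rho, two-sided p)``.
    """
    if feature_name not in FEATURE_NAMES:
        raise FeatureError(f"unknown feature {feature_name!r}; choose from {FEATURE_NAMES}")
    members = [
        r for r in features.select(finger=finger, device=device) if r.stage in STAGE_ORDINAL
    ]
    if len(members) < 5:
        raise FeatureError("need at least 5 staged subjects")
    ordinals = np.array([STAGE_ORDINAL[r.stage] for r in members], dtype=float)
    values = np.array([getattr(r, feature_name) for r in members], dtype=float)
    if len(set(ordinals)) < 2:
        raise FeatureError("all subjects share one stage: correlation undefined")
    if np.ptp(values) == 0:
        raise FeatureError("feature constant across subjects: correlation undefined")
    rho, p = stats.spearmanr(ordinals, values)
    return float(rho), float(p)
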