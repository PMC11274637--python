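"""Joint-angle computation from landmark triples, ROM clamping, velocity.

The flexion angle at a joint B flanked by landmarks A and C is the angle
between the segment vectors AB and BC:

    d1 = AB . BC
    d2 = |AB| |BC|
    angle = arccos(d1 / d2)

With this convention a straight finger (A, B, C collinear, same direction)
scores 0 degrees and flexion grows toward 90-100 degrees.  The arccos
argument is clipped to [-1, 1] to absorb floating-point rounding at exact
collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import JointAngleSeries, LandmarkSequence


class DegenerateGeometryError(ValueError):
    """A landmark triple with a zero-length segment has no defined angle."""


def joint_angle(a, b, c) -> float:
    """Included angle in degrees between segments A->B and B->C.

    Invariant under global rotation, translation and uniform scaling of the
    three points, and symmetric in (a, c).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ab = b - a
    bc = c - b
    n1 = np.linalg.norm(ab)
    n2 = np.linalg.norm(bc)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("coincident landmarks: zero-length segment")
    cosang = np.clip(np.dot(ab, bc) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(seq: LandmarkSequence, finger: str) -> JointAngleSeries:
    """PIP-equivalent angle trace for ``finger``, clamped to the schema ROM.

    One angle per frame from the schema's (A, B, C) landmark triple; any
    frame with a zero-length segment raises naming the frame index.
    """
    if finger not in seq.schema.joint_triples:
        raise KeyError(f"finger {finger!r} not keyed in schema {seq.schema.name!r}")
    ia, ib, ic = seq.schema.joint_triples[finger]
    a = seq.coords[:, ia, :]
    b = seq.coords[:, ib, :]
    c = seq.coords[:, ic, :]
    ab = b - a
    bc = c - b
    n1 = np.linalg.norm(ab, axis=1)
    n2 = np.linalg.norm(bc, axis=1)
    bad = np.flatnonzero((n1 == 0.0) | (n2 == 0.0))
    if bad.size:
        raise DegenerateGeometryError(f"zero-length segment at frame {int(bad[0])}")
    cosang = np.clip(np.einsum("ij,ij->i", ab, bc) / (n1 * n2), -1.0, 1.0)
    series = JointAngleSeries(
        finger=finger,
        fps=seq.fps,
        angles=np.degrees(np.arccos(cosang)),
        rom_cap_deg=seq.schema.rom_cap_deg,
        subject_id=seq.subject_id,
        stage=seq.stage,
    )
    return clamp_rom(series)


def clamp_rom(series: JointAngleSeries) -> JointAngleSeries:
    """Clamp angles above the device's observable ROM down to the cap.

    ``min(angle, rom_cap_deg)`` elementwise; idempotent and monotone.
    """
    return series.with_angles(np.minimum(series.angles, series.rom_cap_deg))


@dataclass
class VelocitySeries:
    """Angular speed (magnitude of the angle derivative) in deg/s."""

    finger: str
    fps: float
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)

    def __len__(self) -> int:
        return len(self.speed)


def angular_velocity(series: JointAngleSeries) -> VelocitySeries:
    """Angular speed via central differences (one-sided at the endpoints).

    ``speed[i] = |dtheta/dt|`` in deg/s; length equals the angle series.
    """
    if len(series) < 2:
        raise ValueError("angular velocity needs at least 2 samples")
    deriv = np.gradient(series.angles) * series.fps
    return VelocitySeries(finger=series.finger, fps=series.fps, speed=np.abs(deriv))
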