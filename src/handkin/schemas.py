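"""Hand landmark schemas for the two device families.

A :class:`HandSchema` names the landmark layout of a device, the landmark
triple (A, B, C) that defines the PIP-equivalent flexion angle of each
finger, the device's observable range of motion, and its native frame rate.

Two schemas ship with the package as JSON documents:

``mediapipe21``
    The canonical 21-landmark monocular-camera hand layout (wrist + four
    landmarks per finger).  The PIP angle of each finger is taken at the
    middle hinge joint; for the thumb, which has no PIP, the IP joint is the
    anatomical equivalent.

``infrared24``
    A 24-landmark layout for an infrared binocular depth device that also
    tracks metacarpals and arm reference points.  The device community has
    not published a single fixed ordering, so the shipped layout is a
    declared convention (four arm/palm reference points followed by four
    landmarks per finger); users of other layouts can load their own JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

FINGERS = ("thumb", "index", "middle", "ring", "pinky")

VALID_N_LANDMARKS = frozenset({21, 24})
VALID_ROM_CAPS = frozenset({90.0, 180.0})
VALID_FPS = frozenset({30.0, 60.0})


class SchemaError(ValueError):
    """Raised for an invalid schema definition or a schema/file mismatch."""


@dataclass(frozen=True)
class HandSchema:
    """Landmark layout and angle-defining triples for one device family.

    Parameters
    ----------
    name
        Identifier of the layout, e.g. ``"mediapipe21"``.
    n_landmarks
        Number of landmarks per frame (21 or 24).
    joint_triples
        Mapping finger name -> ordered landmark-index triple ``(A, B, C)``
        whose included angle at B is the finger's PIP-equivalent flexion.
    rom_cap_deg
        Observable joint range of motion in degrees (180 or 90).  Angles
        beyond the cap are clamped downstream.
    native_fps
        Native recording rate in frames per second (30 or 60).
    """

    name: str
    n_landmarks: int
    joint_triples: Mapping[str, tuple[int, int, int]]
    rom_cap_deg: float
    native_fps: float
    landmark_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_landmarks not in VALID_N_LANDMARKS:
            raise SchemaError(f"n_landmarks must be one of {sorted(VALID_N_LANDMARKS)}, got {self.n_landmarks}")
        if float(self.rom_cap_deg) not in VALID_ROM_CAPS:
            raise SchemaError(f"rom_cap_deg must be 90 or 180, got {self.rom_cap_deg}")
        if float(self.native_fps) not in VALID_FPS:
            raise SchemaError(f"native_fps must be 30 or 60, got {self.native_fps}")
        if set(self.joint_triples) != set(FINGERS):
            raise SchemaError(f"joint_triples must key exactly {FINGERS}, got {tuple(self.joint_triples)}")
        triples = {}
        for finger, triple in self.joint_triples.items():
            triple = tuple(int(i) for i in triple)
            if len(triple) != 3 or len(set(triple)) != 3:
                raise SchemaError(f"{finger}: triple {triple} must be three distinct indices")
            if any(i < 0 or i >= self.n_landmarks for i in triple):
                raise SchemaError(f"{finger}: triple {triple} out of range for {self.n_landmarks} landmarks")
            triples[finger] = triple
        object.__setattr__(self, "joint_triples", triples)
        if self.landmark_names:
            names = tuple(self.landmark_names)
            if len(names) != self.n_landmarks:
                raise SchemaError("landmark_names length must equal n_landmarks")
            object.__setattr__(self, "landmark_names", names)
        else:
            object.__setattr__(
                self, "landmark_names", tuple(f"lm{i:02d}" for i in range(self.n_landmarks))
            )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "name": self.name,
            "n_landmarks": self.n_landmarks,
            "joint_triples": {f: list(t) for f, t in self.joint_triples.items()},
            "rom_cap_deg": self.rom_cap_deg,
            "native_fps": self.native_fps,
            "landmark_names": list(self.landmark_names),
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path

    @classmethod
    def from_dict(cls, doc: Mapping) -> "HandSchema":
        return cls(
            name=doc["name"],
            n_landmarks=int(doc["n_landmarks"]),
            joint_triples={f: tuple(t) for f, t in doc["joint_triples"].items()},
            rom_cap_deg=float(doc["rom_cap_deg"]),
            native_fps=float(doc["native_fps"]),
            landmark_names=tuple(doc.get("landmark_names", ())),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HandSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _load_builtin(name: str) -> HandSchema:
    text = resources.files("handkin.data").joinpath(f"{name}.json").read_text()
    return HandSchema.from_dict(json.loads(text))


def mediapipe21() -> HandSchema:
    """The 21-landmark monocular-camera schema (180-degree ROM, 30 fps)."""
    return _load_builtin("mediapipe21")


def infrared24() -> HandSchema:
    """The 24-landmark infrared binocular schema (90-degree ROM cap, 60 fps)."""
    return _load_builtin("infrared24")


def builtin_schema(name: str) -> HandSchema:
    """Look up a shipped schema by name (``mediapipe21`` or ``infrared24``)."""
    try:
        return _load_builtin(name)
    except FileNotFoundError:
        raise SchemaError(f"no built-in schema named {name!r}") from None
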