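"""Skeleton-driven gesture control.

The interaction model mirrors a Kinect-style natural-user interface for
exploring 3D anatomy.  Both hands are tracked relative to the LEFT
shoulder.  Each hand owns a virtual *control cube*: a preset offset
from the shoulder defines the cube centre, and the hand's displacement
from that centre — normalised by the cube half-width — drives motion.
At the centre nothing moves (a spherical dead zone); away from the
centre, velocity is proportional to the displacement.  If a hand stays
outside its cube for longer than a timeout ("several seconds"), motion
control is disabled until the hand returns to the centre reference
position.

Three modes form the state machine:

* ``NAVIGATE`` — left hand translates the camera, right hand rotates it.
* ``SELECT``   — entered by tapping the left shoulder with the right
  hand; the left hand steers a picking sphere that highlights the
  nearest structure.
* ``MANIPULATE`` — a second tap with a structure highlighted selects it;
  the left hand then translates and the right hand rotates that object
  alone.  A further tap deselects and returns to ``NAVIGATE``.

A ``mode_change`` event carried on a frame (the replay stand-in for a
voice command) triggers the same transition as a shoulder tap.

Coordinate convention for skeleton data: metres, x to the user's
right, y up, z from the user toward the sensor (hands held out in
front of the body have negative z offsets from the shoulders).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = [
    "KINECT_JOINTS",
    "SkeletonFrame",
    "ControlCube",
    "ControllerConfig",
    "ControllerState",
    "Command",
    "TapDetector",
    "cube_offset",
    "offset_to_velocity",
    "detect_shoulder_tap",
    "step_controller",
    "pick_nearest",
    "read_stream",
    "write_stream",
    "controller_config_from_dict",
    "load_controller_config",
    "DEFAULT_LEFT_CUBE",
    "DEFAULT_RIGHT_CUBE",
]

#: The 20 joints of first-generation Kinect skeleton tracking.  Only the
#: hands and shoulders are consumed by the controller; the rest are kept
#: so streams are faithful to what the sensor reports.
KINECT_JOINTS = (
    "hip_center", "spine", "shoulder_center", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "hip_left", "knee_left", "ankle_left", "foot_left",
    "hip_right", "knee_right", "ankle_right", "foot_right",
)

NAVIGATE = "NAVIGATE"
SELECT = "SELECT"
MANIPULATE = "MANIPULATE"


@dataclass
class SkeletonFrame:
    """One timestamped sample of named joint positions (metres)."""

    timestamp: float
    joints: dict[str, np.ndarray]
    tracked: dict[str, bool] = field(default_factory=dict)
    events: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamps must be non-negative")
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        for name in self.joints:
            self.tracked.setdefault(name, True)
        self.events = tuple(self.events)

    def position(self, joint: str) -> np.ndarray | None:
        """Joint position, or None when absent/untracked."""
        if joint not in self.joints or not self.tracked.get(joint, False):
            return None
        return self.joints[joint]


@dataclass(frozen=True)
class ControlCube:
    """A hand-sized cube centred at ``left shoulder + preset_offset``."""

    preset_offset: tuple[float, float, float]
    half_width: float = 0.15  # m
    deadzone: float = 0.15  # fraction of half_width, [0, 1)

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not (0.0 <= self.deadzone < 1.0):
            raise ValueError("deadzone must lie in [0, 1)")


# Cube centres sit a forearm's length in front of and below the
# shoulders; both are referenced to the LEFT shoulder, so the
# right-hand cube's lateral offset spans the body width.
DEFAULT_LEFT_CUBE = ControlCube(preset_offset=(-0.05, -0.25, -0.35))
DEFAULT_RIGHT_CUBE = ControlCube(preset_offset=(0.41, -0.25, -0.35))


@dataclass(frozen=True)
class ControllerConfig:
    """All tunables of the interaction engine.

    Gains are full-scale values: the velocity at a hand offset of one
    half-width.  ``scene_objects`` is the static pick table used for
    highlighting in SELECT mode: ``(object id, centroid in scene mm)``.
    """

    left_cube: ControlCube = DEFAULT_LEFT_CUBE
    right_cube: ControlCube = DEFAULT_RIGHT_CUBE
    translate_gain: float = 0.5       # scene units/s at full scale
    rotate_gain: float = math.pi / 2  # rad/s at full scale (90 deg/s)
    sphere_gain: float = 20.0         # scene units/s for the picking sphere
    timeout: float = 3.0              # s outside the cube before disable
    recenter_radius: float = 0.15     # offset magnitude that re-enables
    tap_radius: float = 0.15          # m, strict inequality
    tap_dwell: float = 0.1            # s the hand must stay on the shoulder
    highlight_max_dist: float = 1e9   # scene units
    scene_objects: tuple[tuple[Any, tuple[float, float, float]], ...] = ()

    def cube(self, hand: str) -> ControlCube:
        return self.left_cube if hand == "left" else self.right_cube


@dataclass
class ControllerState:
    """Mutable interaction state threaded through :func:`step_controller`."""

    mode: str = NAVIGATE
    motion_enabled: bool = True
    out_of_cube_since: dict[str, float | None] = field(
        default_factory=lambda: {"left": None, "right": None})
    highlighted: Any | None = None
    selected: Any | None = None
    sphere_pos: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # tap debounce: the hand must be seen outside the radius before an
    # entry can fire, and each entry fires at most once
    tap_armed: bool = False
    tap_inside_since: float | None = None
    tap_fired: bool = False
    last_t: float | None = None

    def copy(self) -> "ControllerState":
        return dataclasses.replace(
            self,
            out_of_cube_since=dict(self.out_of_cube_since),
            sphere_pos=self.sphere_pos.copy(),
        )


@dataclass(frozen=True)
class Command:
    """A scene edit emitted by the controller.

    ``kind`` is one of camera_translate, camera_rotate, move_sphere,
    highlight, select, deselect, object_translate, object_rotate,
    mode_change; the payload is a velocity triple (units/s or rad/s),
    an object id, or a mode name, matching the kind.
    """

    kind: str
    payload: Any = None

    def to_json(self) -> dict:
        payload = self.payload
        if isinstance(payload, np.ndarray):
            payload = [float(x) for x in payload]
        return {"kind": self.kind, "payload": payload}


def cube_offset(frame: SkeletonFrame, hand: str, cube: ControlCube) -> np.ndarray | None:
    """Normalised hand displacement from the cube centre.

    ``(hand - (left_shoulder + preset_offset)) / half_width`` per
    component, NOT clamped: any component beyond +-1 means the hand is
    outside the cube.  Returns None when a required joint is untracked.
    """
    if hand not in ("left", "right"):
        raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")
    shoulder = frame.position("shoulder_left")
    hand_pos = frame.position(f"hand_{hand}")
    if shoulder is None or hand_pos is None:
        return None
    center = shoulder + np.asarray(cube.preset_offset, dtype=float)
    return (hand_pos - center) / cube.half_width


def offset_to_velocity(offset: Sequence[float], gain: float, deadzone: float) -> np.ndarray:
    """Proportional mapping with a spherical dead zone.

    Zero whenever the Euclidean offset magnitude is within the dead
    zone; otherwise ``gain * offset`` componentwise, so speed grows
    linearly with the hand's distance from the cube centre.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    offset = np.asarray(offset, dtype=float)
    if np.linalg.norm(offset) <= deadzone:
        return np.zeros(3)
    return gain * offset


class TapDetector:
    """Stateful left-shoulder tap detector with debounce.

    A tap fires when the right hand stays strictly within ``tap_radius``
    of the left shoulder for at least ``dwell`` seconds, and only if the
    hand was seen outside the radius since the last entry (one event per
    entry).
    """

    def __init__(self, tap_radius: float = 0.15, dwell: float = 0.1) -> None:
        self.tap_radius = tap_radius
        self.dwell = dwell
        self.armed = False
        self.inside_since: float | None = None
        self.fired = False

    def update(self, frame: SkeletonFrame) -> bool:
        hand = frame.position("hand_right")
        shoulder = frame.position("shoulder_left")
        if hand is None or shoulder is None:
            return False
        inside = float(np.linalg.norm(hand - shoulder)) < self.tap_radius
        if not inside:
            self.armed = True
            self.inside_since = None
            self.fired = False
            return False
        if not self.armed:
            return False
        if self.inside_since is None:
            self.inside_since = frame.timestamp
        if not self.fired and frame.timestamp - self.inside_since >= self.dwell:
            self.fired = True
            return True
        return False


def detect_shoulder_tap(window: Iterable[SkeletonFrame],
                        tap_radius: float = 0.15, dwell: float = 0.1) -> bool:
    """True iff the time-ordered window contains a completed tap."""
    det = TapDetector(tap_radius, dwell)
    return any(det.update(f) for f in window)


def pick_nearest(objects: Sequence[tuple[Any, Sequence[float]]],
                 sphere_pos: Sequence[float], max_dist: float) -> Any | None:
    """Id of the object centroid nearest the sphere within ``max_dist``;
    exact distance ties break toward the lowest id."""
    sphere_pos = np.asarray(sphere_pos, dtype=float)
    best: tuple[float, Any] | None = None
    for obj_id, centroid in objects:
        d = float(np.linalg.norm(np.asarray(centroid, dtype=float) - sphere_pos))
        if d > max_dist:
            continue
        if best is None or d < best[0] or (d == best[0] and obj_id < best[1]):
            best = (d, obj_id)
    return None if best is None else best[1]


def _update_tap(state: ControllerState, frame: SkeletonFrame,
                config: ControllerConfig) -> bool:
    det = TapDetector(config.tap_radius, config.tap_dwell)
    det.armed = state.tap_armed
    det.inside_since = state.tap_inside_since
    det.fired = state.tap_fired
    event = det.update(frame)
    state.tap_armed = det.armed
    state.tap_inside_since = det.inside_since
    state.tap_fired = det.fired
    return event


def _update_motion_gate(state: ControllerState, frame: SkeletonFrame,
                        config: ControllerConfig,
                        offsets: dict[str, np.ndarray | None]) -> None:
    """Per-hand out-of-cube timers plus the global enable latch."""
    t = frame.timestamp
    available = {h: o for h, o in offsets.items() if o is not None}
    for hand, off in available.items():
        if bool(np.any(np.abs(off) > 1.0)):
            since = state.out_of_cube_since[hand]
            if since is None:
                state.out_of_cube_since[hand] = t
            elif t - since > config.timeout:
                state.motion_enabled = False
        else:
            state.out_of_cube_since[hand] = None
    if not state.motion_enabled and available:
        # re-enable only from the centre reference position, every
        # tracked hand back within the recentre radius
        if all(np.linalg.norm(o) <= config.recenter_radius for o in available.values()):
            state.motion_enabled = True


def step_controller(state: ControllerState, frame: SkeletonFrame,
                    config: ControllerConfig) -> tuple[ControllerState, list[Command]]:
    """Advance the interaction state machine by one skeleton frame.

    Frames must arrive in strictly increasing timestamp order.  Returns
    the successor state and the commands to apply to the scene; the
    input state is not mutated.
    """
    if state.last_t is not None and frame.timestamp <= state.last_t:
        raise ValueError(
            f"out-of-order frame: t={frame.timestamp} after t={state.last_t}")
    new = state.copy()
    dt = 0.0 if new.last_t is None else frame.timestamp - new.last_t
    new.last_t = frame.timestamp
    commands: list[Command] = []

    tap = _update_tap(new, frame, config) or ("mode_change" in frame.events)
    if tap:
        if new.mode == NAVIGATE:
            new.mode = SELECT
            new.highlighted = None
            commands.append(Command("mode_change", SELECT))
        elif new.mode == SELECT:
            if new.highlighted is not None:
                new.selected = new.highlighted
                new.highlighted = None
                new.mode = MANIPULATE
                commands.append(Command("select", new.selected))
                commands.append(Command("mode_change", MANIPULATE))
            # tap with nothing highlighted: stay in SELECT
        else:  # MANIPULATE
            commands.append(Command("deselect", new.selected))
            new.selected = None
            new.mode = NAVIGATE
            commands.append(Command("mode_change", NAVIGATE))

    offsets = {
        "left": cube_offset(frame, "left", config.left_cube),
        "right": cube_offset(frame, "right", config.right_cube),
    }
    _update_motion_gate(new, frame, config, offsets)

    if new.motion_enabled:
        # a hand outside its cube contributes no motion: the cube bounds
        # the control range, and only the out-of-cube timer runs
        left, right = (
            None if off is None or np.any(np.abs(off) > 1.0) else off
            for off in (offsets["left"], offsets["right"])
        )
        if new.mode == NAVIGATE:
            if left is not None:
                v = offset_to_velocity(left, config.translate_gain, config.left_cube.deadzone)
                if np.any(v):
                    commands.append(Command("camera_translate", v))
            if right is not None:
                w = offset_to_velocity(right, config.rotate_gain, config.right_cube.deadzone)
                if np.any(w):
                    commands.append(Command("camera_rotate", w))
        elif new.mode == SELECT:
            if left is not None:
                v = offset_to_velocity(left, config.sphere_gain, config.left_cube.deadzone)
                if np.any(v):
                    commands.append(Command("move_sphere", v))
                    new.sphere_pos = new.sphere_pos + v * dt
            if config.scene_objects:
                picked = pick_nearest(config.scene_objects, new.sphere_pos,
                                      config.highlight_max_dist)
                if picked != new.highlighted:
                    new.highlighted = picked
                    commands.append(Command("highlight", picked))
        else:  # MANIPULATE
            if left is not None:
                v = offset_to_velocity(left, config.translate_gain, config.left_cube.deadzone)
                if np.any(v):
                    commands.append(Command("object_translate", v))
            if right is not None:
                w = offset_to_velocity(right, config.rotate_gain, config.right_cube.deadzone)
                if np.any(w):
                    commands.append(Command("object_rotate", w))
    return new, commands


# ---------------------------------------------------------------------------
# Stream serialization: line-delimited JSON, one frame per line:
#   {"t": seconds, "joints": {"hand_left": [x, y, z], ...},
#    "events": ["mode_change"]}        (events key optional)
# Joints listed are tracked; untracked joints are simply omitted.
# ---------------------------------------------------------------------------

def write_stream(frames: Iterable[SkeletonFrame], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        for f in frames:
            rec: dict[str, Any] = {
                "t": float(f.timestamp),
                "joints": {k: [float(x) for x in v]
                           for k, v in f.joints.items() if f.tracked.get(k, False)},
            }
            if f.events:
                rec["events"] = list(f.events)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def controller_config_from_dict(raw: dict) -> ControllerConfig:
    """Build a :class:`ControllerConfig` from plain JSON data; cube
    entries are objects with ``preset_offset``, ``half_width``,
    ``deadzone``."""
    kwargs: dict[str, Any] = {}
    for side in ("left_cube", "right_cube"):
        if side in raw:
            c = dict(raw[side])
            c["preset_offset"] = tuple(c["preset_offset"])
            kwargs[side] = ControlCube(**c)
    for key in ("translate_gain", "rotate_gain", "sphere_gain", "timeout",
                "recenter_radius", "tap_radius", "tap_dwell", "highlight_max_dist"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return ControllerConfig(**kwargs)


def load_controller_config(path: str | os.PathLike) -> ControllerConfig:
    with open(os.fspath(path)) as fh:
        return controller_config_from_dict(json.load(fh))


def read_stream(path: str | os.PathLike) -> list[SkeletonFrame]:
    frames: list[SkeletonFrame] = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"bad stream line {lineno}: {exc}") from exc
            frames.append(SkeletonFrame(
                timestamp=float(rec["t"]),
                joints={k: np.asarray(v, dtype=float) for k, v in rec["joints"].items()},
                events=tuple(rec.get("events", ())),
            ))
    return frames
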