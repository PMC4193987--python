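"""The 3D scene: camera and object poses, command integration, replay.

Conventions (fixed so the stereo math is unambiguous): right-handed
coordinates, scene units are millimetres (matching mesh export), and
the camera looks down its body-frame -z axis with y up.  Controller
velocities are body-frame (egocentric): a forward translate command
moves the camera along its own -z, and angular velocities compose on
the right of the current orientation (body-frame rotation).

Poses carry unit quaternions in (w, x, y, z) order; integration
renormalizes each step so the norm never drifts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .gesture import (Command, ControllerConfig, ControllerState, SkeletonFrame,
                      step_controller)
from .meshing import TriMesh

__all__ = [
    "Pose",
    "SceneObject",
    "Scene",
    "TransformLog",
    "integrate_pose",
    "apply_command",
    "replay",
]


def _quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("zero quaternion")
    return q / n


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def _quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis * angle, radians)."""
    angle = np.linalg.norm(rv)
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = rv / angle
    half = angle / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _quat_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class Pose:
    """Rigid transform: position (scene mm) + unit quaternion (w,x,y,z)."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError(
                f"orientation must be a unit quaternion, |q| = {np.linalg.norm(self.orientation)}")

    def rotation_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the body axes in world frame."""
        return _quat_matrix(self.orientation)

    def copy(self) -> "Pose":
        return Pose(self.position.copy(), self.orientation.copy())

    def to_json(self) -> dict:
        return {
            "position": [float(x) for x in self.position],
            "orientation": [float(x) for x in self.orientation],
        }


def _so3_left_jacobian(rv: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3) at rotation vector rv: integrates a
    body-frame direction along the rotational flow."""
    theta = np.linalg.norm(rv)
    K = np.array([[0, -rv[2], rv[1]], [rv[2], 0, -rv[0]], [-rv[1], rv[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + K / 2.0 + K @ K / 6.0
    return (np.eye(3) + (1 - np.cos(theta)) / theta ** 2 * K
            + (theta - np.sin(theta)) / theta ** 3 * (K @ K))


def integrate_pose(pose: Pose, linear_vel: Sequence[float],
                   angular_vel: Sequence[float], dt: float) -> Pose:
    """Advance a pose by constant body-frame velocities over dt seconds.

    This is the exact flow of the constant twist (screw motion):
    ``q <- q * exp(angular_vel * dt)`` and ``position += R(q) @
    J(angular_vel * dt) @ linear_vel * dt`` with J the SO(3) left
    Jacobian, followed by quaternion renormalization.  Being the exact
    flow, two half-steps compose to one full step; with zero angular
    velocity it reduces to ``position += R(q) @ linear_vel * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(linear_vel, dtype=float)
    w = np.asarray(angular_vel, dtype=float)
    rv = w * dt
    new_pos = pose.position + pose.rotation_matrix() @ (_so3_left_jacobian(rv) @ (v * dt))
    dq = _quat_from_rotvec(rv)
    new_q = _quat_normalize(_quat_multiply(pose.orientation, dq))
    return Pose(new_pos, new_q)


@dataclass
class SceneObject:
    name: str
    mesh: TriMesh | None = None
    pose: Pose = field(default_factory=Pose)
    highlighted: bool = False
    selected: bool = False

    def centroid(self) -> np.ndarray:
        """World-space pick centroid (mesh centroid moved by the pose)."""
        base = self.mesh.centroid() if self.mesh is not None else np.zeros(3)
        return self.pose.position + self.pose.rotation_matrix() @ base


@dataclass
class Scene:
    """Objects by id, the camera, and the selection-sphere position."""

    objects: dict[str, SceneObject] = field(default_factory=dict)
    camera: Pose = field(default_factory=Pose)
    sphere_pos: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.sphere_pos = np.asarray(self.sphere_pos, dtype=float).reshape(3)
        if sum(o.selected for o in self.objects.values()) > 1:
            raise ValueError("at most one object may be selected")
        if sum(o.highlighted for o in self.objects.values()) > 1:
            raise ValueError("at most one object may be highlighted")

    def selected_id(self) -> str | None:
        for oid, o in self.objects.items():
            if o.selected:
                return oid
        return None

    def highlighted_id(self) -> str | None:
        for oid, o in self.objects.items():
            if o.highlighted:
                return oid
        return None

    def centroids(self) -> tuple[tuple[str, tuple[float, float, float]], ...]:
        return tuple(
            (oid, tuple(float(x) for x in obj.centroid()))
            for oid, obj in sorted(self.objects.items())
        )


def apply_command(scene: Scene, cmd: Command, dt: float) -> Scene:
    """Apply one controller command to the scene (mutated in place and
    returned).

    Camera commands move the camera, object commands move only the
    selected object, highlight/select/deselect maintain the
    single-selection invariant; ``mode_change`` has no scene effect
    (it is recorded by the replay log).  ``dt`` scales velocity
    payloads; a dt of 0 (first frame) leaves poses unchanged.
    """
    kind = cmd.kind
    if kind in ("camera_translate", "camera_rotate", "move_sphere",
                "object_translate", "object_rotate") and dt == 0:
        return scene
    if kind == "camera_translate":
        scene.camera = integrate_pose(scene.camera, cmd.payload, np.zeros(3), dt)
    elif kind == "camera_rotate":
        scene.camera = integrate_pose(scene.camera, np.zeros(3), cmd.payload, dt)
    elif kind == "move_sphere":
        scene.sphere_pos = scene.sphere_pos + np.asarray(cmd.payload, float) * dt
    elif kind == "highlight":
        for o in scene.objects.values():
            o.highlighted = False
        if cmd.payload is not None:
            if cmd.payload not in scene.objects:
                raise KeyError(f"cannot highlight unknown object {cmd.payload!r}")
            scene.objects[cmd.payload].highlighted = True
    elif kind == "select":
        if cmd.payload not in scene.objects:
            raise KeyError(f"cannot select unknown object {cmd.payload!r}")
        for o in scene.objects.values():
            o.selected = False
            o.highlighted = False
        scene.objects[cmd.payload].selected = True
    elif kind == "deselect":
        for o in scene.objects.values():
            o.selected = False
    elif kind in ("object_translate", "object_rotate"):
        oid = scene.selected_id()
        if oid is None:
            raise ValueError(f"{kind} with no selected object")
        obj = scene.objects[oid]
        if kind == "object_translate":
            obj.pose = integrate_pose(obj.pose, cmd.payload, np.zeros(3), dt)
        else:
            obj.pose = integrate_pose(obj.pose, np.zeros(3), cmd.payload, dt)
    elif kind == "mode_change":
        pass
    else:
        raise ValueError(f"unknown command kind {kind!r}")
    return scene


@dataclass
class TransformLog:
    """Per-frame record of every pose, the mode, and emitted commands."""

    records: list[dict] = field(default_factory=list)

    def to_jsonl(self) -> str:
        return "".join(json.dumps(r, sort_keys=True) + "\n" for r in self.records)

    def write(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(self.to_jsonl())

    def final_camera(self) -> Pose:
        rec = self.records[-1]["camera"]
        return Pose(np.array(rec["position"]), np.array(rec["orientation"]))

    def final_object_pose(self, oid: str) -> Pose:
        rec = self.records[-1]["objects"][oid]
        return Pose(np.array(rec["position"]), np.array(rec["orientation"]))


def _record(scene: Scene, t: float | None, mode: str,
            commands: list[Command], initial: bool = False) -> dict:
    return {
        "t": t,
        "initial": initial,
        "mode": mode,
        "camera": scene.camera.to_json(),
        "sphere": [float(x) for x in scene.sphere_pos],
        "objects": {oid: obj.pose.to_json() for oid, obj in sorted(scene.objects.items())},
        "highlighted": scene.highlighted_id(),
        "selected": scene.selected_id(),
        "events": [c.to_json() for c in commands],
    }


def replay(scene: Scene, stream: Sequence[SkeletonFrame],
           config: ControllerConfig | None = None,
           state: ControllerState | None = None) -> TransformLog:
    """Drive the whole session: every frame goes through the controller
    and its commands are integrated into the scene.

    ``dt`` comes from consecutive stream timestamps (which must be
    strictly increasing; the controller raises otherwise).  Object
    meshes are never mutated — only poses change.  The log starts with
    the initial scene state, then one record per frame; identical
    inputs yield byte-identical logs.
    """
    if config is None:
        config = ControllerConfig()
    if not config.scene_objects and scene.objects:
        config = replace(config, scene_objects=scene.centroids())
    if state is None:
        state = ControllerState(sphere_pos=scene.sphere_pos.copy())
    log = TransformLog()
    log.records.append(_record(scene, None, state.mode, [], initial=True))
    prev_t: float | None = None
    for frame in stream:
        state, commands = step_controller(state, frame, config)
        dt = 0.0 if prev_t is None else frame.timestamp - prev_t
        prev_t = frame.timestamp
        for cmd in commands:
            apply_command(scene, cmd, dt)
        log.records.append(_record(scene, float(frame.timestamp), state.mode, commands))
    return log
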