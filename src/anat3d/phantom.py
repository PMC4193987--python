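"""Synthetic test data: a temporal-bone-like CT phantom and scripted
skeleton streams.

The CT phantom emulates a micro-CT acquisition of a cadaveric temporal
bone at 0.15 mm isotropic voxels: an air background (~-1000 HU), a
dense bone block (~1500 HU) pierced by a soft-tissue canal (~-30 HU, a
facial-nerve stand-in), a one-voxel-thick membrane spanning the canal
(~-70 HU, the tympanic-membrane stand-in that later gets thickened to
2-3 voxels), and small high-density ossicle ellipsoids (~2000 HU) in
the air cavity.  Default intensities sit strictly inside the standard
segmentation windows (bone 382..3071 HU inclusive; membrane below
-50 HU), so with zero noise threshold presets recover the generating
labels exactly — the pipeline's parameter-recovery benchmark.  The
label map returned alongside the volume IS the generating geometry.

The skeleton generator emulates 30 Hz Kinect-style joint tracking of a
standing user, with scripted motion primitives (hold a hand at a cube
offset, recentre, tap the left shoulder, leave the cube, idle) so every
controller behaviour can be exercised deterministically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .gesture import (DEFAULT_LEFT_CUBE, DEFAULT_RIGHT_CUBE, KINECT_JOINTS,
                      ControlCube, SkeletonFrame)
from .volume_io import LabelMap, Volume

__all__ = [
    "PhantomSpec",
    "Ellipsoid",
    "MotionScript",
    "make_ct_phantom",
    "make_skeleton_stream",
    "load_script",
    "BASE_SKELETON",
    "STRUCTURE_NAMES",
]

STRUCTURE_NAMES = ("temporal_bone", "facial_nerve", "tympanic_membrane", "ossicles")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel index space."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Geometry and intensities of the synthetic temporal-bone volume.

    All positions/sizes are in voxels of the stated spacing; HU values
    must be pairwise distinct (and distinct from the background) so a
    noise-free phantom is exactly separable by thresholding.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.15, 0.15, 0.15)  # mm
    noise_sd: float = 0.0  # HU

    # intensities (HU)
    air_hu: float = -1000.0
    bone_hu: float = 1500.0
    canal_hu: float = -30.0
    membrane_hu: float = -70.0
    ossicle_hu: float = 2000.0

    # geometry (voxel indices; x, y, z order).  Ossicle semi-axes are at
    # anatomical scale: ~1-2.5 mm bodies, i.e. 5-8 voxels at 0.15 mm.
    include_bone: bool = True
    include_canal: bool = True
    include_membrane: bool = True
    include_ossicles: bool = True
    bone_margin: int = 5            # air border around the bone block in x/y
    bone_z: tuple[int, int] = (10, 34)  # bone slab spans z in [z0, z1)
    canal_radius: float = 6.0       # voxels, tube along z through the slab
    membrane_z: int = 22            # the one-voxel membrane plane
    membrane_radius: float = 8.0    # voxels, disk spanning the canal mouth
    ossicles: tuple[Ellipsoid, ...] = (
        Ellipsoid(center=(22.0, 32.0, 46.0), semi_axes=(8.0, 6.0, 5.0)),
        Ellipsoid(center=(42.0, 32.0, 48.0), semi_axes=(5.0, 6.0, 7.0)),
    )

    def validate(self) -> None:
        if any(n < 8 for n in self.shape):
            raise ValueError(f"shape {self.shape} too small for the phantom geometry")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        hus = [self.air_hu, self.bone_hu, self.canal_hu, self.membrane_hu, self.ossicle_hu]
        if len(set(hus)) != len(hus):
            raise ValueError(f"structure HU values must be pairwise distinct, got {hus}")
        nx, ny, nz = self.shape
        if self.include_bone:
            if 2 * self.bone_margin >= min(nx, ny):
                raise ValueError("bone margins leave no room for the bone block")
            if not (0 <= self.bone_z[0] < self.bone_z[1] <= nz):
                raise ValueError(f"bone z-range {self.bone_z} does not fit in nz={nz}")
        if self.include_membrane and not (0 <= self.membrane_z < nz):
            raise ValueError(f"membrane plane z={self.membrane_z} outside volume")
        if self.include_canal and 2 * self.canal_radius >= min(nx, ny):
            raise ValueError("canal radius too large for the volume cross-section")
        for e in self.ossicles if self.include_ossicles else ():
            for c, a, n in zip(e.center, e.semi_axes, self.shape):
                if a <= 0:
                    raise ValueError("ossicle semi-axes must be positive")
                if c - a < 0 or c + a > n - 1:
                    raise ValueError(f"ossicle {e} does not fit inside shape {self.shape}")


def make_ct_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[Volume, LabelMap]:
    """Render the phantom: a HU volume plus its ground-truth label map.

    Structures are painted in the order bone, canal, membrane, ossicles,
    with later (more specific) structures overwriting earlier ones —
    the same priority the label-composition step uses.  Gaussian noise
    of sd ``spec.noise_sd`` HU is added with the given seed; generation
    is a pure function of (spec, seed).
    """
    spec.validate()
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    ii, jj, kk = np.mgrid[0:nx, 0:ny, 0:nz]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r2_xy = (ii - cx) ** 2 + (jj - cy) ** 2

    if spec.include_bone:
        m = spec.bone_margin
        bone = (ii >= m) & (ii < nx - m) & (jj >= m) & (jj < ny - m) \
            & (kk >= spec.bone_z[0]) & (kk < spec.bone_z[1])
        labels[bone] = 1
    if spec.include_canal:
        canal = (r2_xy <= spec.canal_radius ** 2) \
            & (kk >= spec.bone_z[0]) & (kk < spec.bone_z[1])
        labels[canal] = 2
    if spec.include_membrane:
        membrane = (r2_xy <= spec.membrane_radius ** 2) & (kk == spec.membrane_z)
        labels[membrane] = 3
    if spec.include_ossicles:
        for e in spec.ossicles:
            d = ((ii - e.center[0]) / e.semi_axes[0]) ** 2 \
                + ((jj - e.center[1]) / e.semi_axes[1]) ** 2 \
                + ((kk - e.center[2]) / e.semi_axes[2]) ** 2
            labels[d <= 1.0] = 4

    hu_of_label = np.array(
        [spec.air_hu, spec.bone_hu, spec.canal_hu, spec.membrane_hu, spec.ossicle_hu])
    data = hu_of_label[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    else:
        data = np.rint(data).astype(np.int16)

    names = {i + 1: n for i, n in enumerate(STRUCTURE_NAMES)}
    vol = Volume(data=data, spacing=spec.spacing)
    gt = LabelMap(data=labels, names=names, spacing=spec.spacing)
    return vol, gt


# ---------------------------------------------------------------------------
# Skeleton streams
# ---------------------------------------------------------------------------

# A neutral standing pose, metres; x right, y up, z toward the sensor.
BASE_SKELETON: dict[str, tuple[float, float, float]] = {
    "hip_center": (0.0, 0.95, 2.0),
    "spine": (0.0, 1.15, 2.0),
    "shoulder_center": (0.0, 1.40, 2.0),
    "head": (0.0, 1.60, 2.0),
    "shoulder_left": (-0.18, 1.40, 2.0),
    "elbow_left": (-0.25, 1.20, 1.95),
    "wrist_left": (-0.24, 1.16, 1.70),
    "hand_left": (-0.23, 1.15, 1.65),
    "shoulder_right": (0.18, 1.40, 2.0),
    "elbow_right": (0.25, 1.20, 1.95),
    "wrist_right": (0.24, 1.16, 1.70),
    "hand_right": (0.23, 1.15, 1.65),
    "hip_left": (-0.12, 0.92, 2.0),
    "knee_left": (-0.13, 0.55, 2.0),
    "ankle_left": (-0.13, 0.12, 2.0),
    "foot_left": (-0.13, 0.05, 1.90),
    "hip_right": (0.12, 0.92, 2.0),
    "knee_right": (0.13, 0.55, 2.0),
    "ankle_right": (0.13, 0.12, 2.0),
    "foot_right": (0.13, 0.05, 1.90),
}

assert set(BASE_SKELETON) == set(KINECT_JOINTS)

_PRIMITIVES = ("idle", "hold_offset", "recenter", "tap_shoulder", "exit_cube",
               "inject_mode")


@dataclass
class MotionScript:
    """Ordered motion primitives that a stream realizes.

    Each step is ``(op, params)`` with op one of: ``idle(duration)``,
    ``hold_offset(hand, offset, duration)``, ``recenter(hand,
    duration)``, ``tap_shoulder(duration)``, ``exit_cube(hand,
    duration)``, ``inject_mode()`` (a single frame carrying a
    ``mode_change`` event, the voice-command stand-in).  Offsets are
    dimensionless cube units; durations are seconds and must be
    positive.
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def _add(self, op: str, **params) -> "MotionScript":
        if op not in _PRIMITIVES:
            raise ValueError(f"unknown primitive {op!r}; expected one of {_PRIMITIVES}")
        duration = params.get("duration")
        if duration is not None and duration <= 0:
            raise ValueError(f"{op}: duration must be > 0, got {duration}")
        offset = params.get("offset")
        if offset is not None and not np.all(np.isfinite(offset)):
            raise ValueError(f"{op}: offset must be finite, got {offset}")
        hand = params.get("hand")
        if hand is not None and hand not in ("left", "right"):
            raise ValueError(f"{op}: hand must be 'left' or 'right', got {hand!r}")
        self.steps.append((op, params))
        return self

    def idle(self, duration: float) -> "MotionScript":
        return self._add("idle", duration=duration)

    def hold_offset(self, hand: str, offset, duration: float) -> "MotionScript":
        return self._add("hold_offset", hand=hand,
                         offset=tuple(float(x) for x in offset), duration=duration)

    def recenter(self, hand: str, duration: float) -> "MotionScript":
        return self._add("recenter", hand=hand, duration=duration)

    def tap_shoulder(self, duration: float) -> "MotionScript":
        return self._add("tap_shoulder", duration=duration)

    def exit_cube(self, hand: str, duration: float) -> "MotionScript":
        return self._add("exit_cube", hand=hand, duration=duration)

    def inject_mode(self) -> "MotionScript":
        return self._add("inject_mode")


def load_script(path: str | os.PathLike) -> MotionScript:
    """Read a script from JSON: a list of ``{"op": ..., params...}``."""
    with open(os.fspath(path)) as fh:
        raw = json.load(fh)
    script = MotionScript()
    for entry in raw:
        entry = dict(entry)
        op = entry.pop("op")
        script._add(op, **entry)
    return script


def _cube_center(cube: ControlCube) -> np.ndarray:
    return np.asarray(BASE_SKELETON["shoulder_left"]) + np.asarray(cube.preset_offset)


def make_skeleton_stream(script: MotionScript, frame_rate: float = 30.0,
                         seed: int = 0, jitter_sd: float = 0.0,
                         left_cube: ControlCube = DEFAULT_LEFT_CUBE,
                         right_cube: ControlCube = DEFAULT_RIGHT_CUBE,
                         ) -> list[SkeletonFrame]:
    """Realize a motion script as uniformly-timed skeleton frames.

    Frames tick at ``frame_rate`` Hz starting at t = 0.  Hands default
    to their cube centres; ``hold_offset`` places a hand at
    ``centre + offset * half_width``; ``tap_shoulder`` puts the right
    hand on the left shoulder; ``exit_cube`` parks the hand two
    half-widths off centre.  Optional isotropic Gaussian jitter of sd
    ``jitter_sd`` metres (seeded) models tracking noise; the default is
    noise-free so tests are exact.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    cubes = {"left": left_cube, "right": right_cube}
    rng = np.random.default_rng(seed)
    frames: list[SkeletonFrame] = []
    frame_idx = 0
    for op, params in script.steps:
        if op == "inject_mode":
            n = 1
        else:
            n = max(1, round(params["duration"] * frame_rate))
        for _ in range(n):
            joints = {k: np.asarray(v, dtype=float) for k, v in BASE_SKELETON.items()}
            joints["hand_left"] = _cube_center(cubes["left"])
            joints["hand_right"] = _cube_center(cubes["right"])
            events: tuple[str, ...] = ()
            if op == "hold_offset":
                cube = cubes[params["hand"]]
                joints[f"hand_{params['hand']}"] = (
                    _cube_center(cube) + np.asarray(params["offset"]) * cube.half_width)
            elif op == "exit_cube":
                cube = cubes[params["hand"]]
                joints[f"hand_{params['hand']}"] = (
                    _cube_center(cube) + np.array([2.0, 0.0, 0.0]) * cube.half_width)
            elif op == "tap_shoulder":
                joints["hand_right"] = np.asarray(BASE_SKELETON["shoulder_left"], float)
            elif op == "inject_mode":
                events = ("mode_change",)
            # idle / recenter: hands stay at cube centres
            if jitter_sd > 0:
                for name in joints:
                    joints[name] = joints[name] + rng.normal(0.0, jitter_sd, 3)
            frames.append(SkeletonFrame(
                timestamp=frame_idx / frame_rate, joints=joints, events=events))
            frame_idx += 1
    return frames
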