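"""Stereoscopic camera mathematics: off-axis projection, parallax,
divergence checking, and the selected-object pop-out adjustment.

The model is standard desktop stereoscopy with parallel camera axes and
asymmetric frusta: the two eyes are displaced by +-e/2 along the
camera's x axis (e = eye_separation * depth_gain, the vendor-style
"depth" knob), and both frusta share the *convergence plane* — the
camera-space depth C at which a point projects to the same screen
position in both eyes.  The convergence plane is mapped 1:1 onto the
physical display, so a point at camera depth z has signed screen
parallax

    p(z) = e * (1 - C / z)     [mm]

which is zero on the convergence plane, negative (in front of the
screen, "popped out") for nearer points, and approaches e from below
as z grows.  Fusion fails when the positive parallax reaches the
viewer's own interocular distance (~65 mm): the eyes would have to
diverge.  ``check_divergence`` audits a scene sample against that
bound and ``popout_adjust`` moves the convergence plane behind a
selected object so it acquires negative parallax without violating
the bound at the scene's far extent.

Toed-in cameras are deliberately not used: converging the camera axes
introduces vertical parallax, which the off-axis construction avoids.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .scene import Pose

__all__ = [
    "StereoParams",
    "EyeView",
    "DivergenceReport",
    "InfeasibleStereoError",
    "stereo_pair",
    "project_point",
    "parallax",
    "check_divergence",
    "popout_adjust",
    "load_stereo_params",
]

#: Mean human interocular distance, mm — the divergence limit.
HUMAN_EYE_SEPARATION_MM = 65.0


class InfeasibleStereoError(ValueError):
    """No convergence distance satisfies all requested constraints."""


@dataclass(frozen=True)
class StereoParams:
    """Stereo rig geometry, all lengths in millimetres.

    ``eye_separation * depth_gain`` is the effective camera-eye
    baseline in scene mm (depth_gain is the dimensionless "depth"
    knob).  ``convergence_distance`` is the camera-space depth of the
    zero-parallax plane (the "convergence" knob).  The screen block
    gives the physical display the convergence plane is mapped onto.
    """

    eye_separation: float = HUMAN_EYE_SEPARATION_MM
    convergence_distance: float = 500.0
    depth_gain: float = 1.0
    screen_width: float = 520.0
    screen_height: float = 320.0
    viewer_distance: float = 600.0

    def __post_init__(self) -> None:
        if self.convergence_distance <= 0:
            raise ValueError("convergence_distance must be > 0")
        if self.eye_separation < 0:
            raise ValueError("eye_separation must be >= 0")
        if self.depth_gain < 0:
            raise ValueError("depth_gain must be >= 0")
        if self.screen_width <= 0 or self.screen_height <= 0 or self.viewer_distance <= 0:
            raise ValueError("screen dimensions and viewer distance must be > 0")

    @property
    def effective_eye_separation(self) -> float:
        return self.eye_separation * self.depth_gain


@dataclass(frozen=True)
class EyeView:
    """View and projection matrices (4x4, OpenGL-style, column vectors)
    for one eye."""

    view: np.ndarray
    projection: np.ndarray


@dataclass(frozen=True)
class DivergenceReport:
    ok: bool
    worst_point: tuple[float, float, float] | None
    worst_parallax: float  # mm on screen
    limit: float  # mm


def _camera_frame(point: Sequence[float], camera: Pose) -> np.ndarray:
    R = camera.rotation_matrix()
    return R.T @ (np.asarray(point, dtype=float) - camera.position)


def _camera_depth(point: Sequence[float], camera: Pose) -> float:
    """Depth along the viewing direction (camera looks down body -z)."""
    return float(-_camera_frame(point, camera)[2])


def _frustum(left: float, right: float, bottom: float, top: float,
             near: float, far: float) -> np.ndarray:
    return np.array([
        [2 * near / (right - left), 0.0, (right + left) / (right - left), 0.0],
        [0.0, 2 * near / (top - bottom), (top + bottom) / (top - bottom), 0.0],
        [0.0, 0.0, -(far + near) / (far - near), -2 * far * near / (far - near)],
        [0.0, 0.0, -1.0, 0.0],
    ])


def stereo_pair(camera: Pose, params: StereoParams,
                near: float | None = None, far: float | None = None,
                ) -> tuple[EyeView, EyeView]:
    """Off-axis view/projection pair for the two eyes.

    Eyes sit at ``camera +- (e/2) * x_body``; each asymmetric frustum is
    chosen so a screen-sized window on the convergence plane, centred on
    the camera axis, fills the viewport in both eyes.  Points on that
    plane therefore land on identical screen coordinates, nearer points
    acquire negative parallax, farther points positive parallax.
    """
    C = params.convergence_distance
    if near is None:
        near = C / 100.0
    if far is None:
        far = C * 100.0
    if not (0 < near < far):
        raise ValueError("need 0 < near < far")
    e = params.effective_eye_separation
    R = camera.rotation_matrix()
    x_axis = R[:, 0]
    half_w, half_h = params.screen_width / 2.0, params.screen_height / 2.0
    views = []
    for sign in (-1.0, +1.0):
        eye_pos = camera.position + sign * (e / 2.0) * x_axis
        view = np.eye(4)
        view[:3, :3] = R.T
        view[:3, 3] = -R.T @ eye_pos
        # window on the convergence plane, relative to this eye
        shift = sign * e / 2.0
        scale = near / C
        proj = _frustum((-half_w - shift) * scale, (half_w - shift) * scale,
                        -half_h * scale, half_h * scale, near, far)
        views.append(EyeView(view=view, projection=proj))
    return views[0], views[1]


def project_point(point: Sequence[float], eye: EyeView) -> np.ndarray:
    """Normalized device coordinates of a world point in one eye."""
    hp = np.append(np.asarray(point, dtype=float), 1.0)
    clip = eye.projection @ (eye.view @ hp)
    if clip[3] <= 0:
        raise ValueError("point is at or behind the eye plane")
    return clip[:3] / clip[3]


def parallax(point: Sequence[float], camera: Pose, params: StereoParams) -> float:
    """Signed screen parallax of a world point, in mm.

    Closed form ``e * (1 - C / z)`` with z the camera-frame depth;
    agrees with the projected left/right screen-coordinate difference
    of :func:`stereo_pair` to numerical precision.
    """
    z = _camera_depth(point, camera)
    if z <= 0:
        raise ValueError(f"point has non-positive camera depth z = {z}")
    return params.effective_eye_separation * (1.0 - params.convergence_distance / z)


def screen_parallax_from_pair(point: Sequence[float], camera: Pose,
                              params: StereoParams) -> float:
    """Parallax measured the long way round, by projecting through both
    eye frusta — the cross-check for the closed form."""
    left, right = stereo_pair(camera, params)
    xl = project_point(point, left)[0]
    xr = project_point(point, right)[0]
    return (xr - xl) * params.screen_width / 2.0


def check_divergence(points: Sequence[Sequence[float]], camera: Pose,
                     params: StereoParams,
                     viewer_eye_separation: float = HUMAN_EYE_SEPARATION_MM,
                     ) -> DivergenceReport:
    """Audit a scene sample for fusion-breaking positive parallax.

    ok iff the maximum positive parallax stays strictly below the
    viewer's interocular distance.  Points at or behind the eye plane
    are not projected and are skipped.
    """
    worst_p = 0.0
    worst_point: tuple[float, float, float] | None = None
    for p in points:
        if _camera_depth(p, camera) <= 0:
            continue
        px = parallax(p, camera, params)
        if worst_point is None or px > worst_p:
            worst_p = px
            worst_point = tuple(float(x) for x in p)
    return DivergenceReport(
        ok=worst_p < viewer_eye_separation,
        worst_point=worst_point,
        worst_parallax=worst_p,
        limit=viewer_eye_separation,
    )


def popout_adjust(params: StereoParams, object_depth: float,
                  far_depth: float | None = None,
                  viewer_eye_separation: float = HUMAN_EYE_SEPARATION_MM,
                  margin: float = 0.1) -> StereoParams:
    """Move the convergence plane behind a selected object so it pops
    out of the screen (strictly negative parallax).

    If the object already sits nearer than the convergence plane the
    params are returned unchanged.  Otherwise the convergence distance
    is raised to ``object_depth * (1 + margin)`` — or further if needed
    to keep the scene's far extent (``far_depth``) under the divergence
    limit.  The crossed-parallax magnitude at the object is held below
    the same viewer limit; when both constraints cannot hold at once an
    :class:`InfeasibleStereoError` names the binding constraint.
    """
    if object_depth <= 0:
        raise ValueError("object_depth must be > 0")
    e = params.effective_eye_separation
    if e == 0:
        raise InfeasibleStereoError(
            "effective eye separation is zero: no convergence distance can "
            "produce negative parallax (binding constraint: eye_separation * depth_gain > 0)")
    if params.convergence_distance > object_depth:
        return params
    lower = object_depth * (1.0 + margin)
    if far_depth is not None and far_depth > 0 and e > viewer_eye_separation:
        # e * (1 - C/z_far) < viewer  =>  C > z_far * (1 - viewer/e)
        lower = max(lower, far_depth * (1.0 - viewer_eye_separation / e) * (1.0 + 1e-9))
    # |e * (1 - C/d)| < viewer  =>  C < d * (1 + viewer/e)
    upper = object_depth * (1.0 + viewer_eye_separation / e)
    if lower >= upper:
        raise InfeasibleStereoError(
            f"no convergence distance satisfies pop-out and divergence bounds: "
            f"need C in [{lower:.3f}, {upper:.3f}) mm "
            f"(binding constraint: far extent {far_depth} mm requires C >= {lower:.3f}, "
            f"but crossed parallax at the object caps C below {upper:.3f})")
    return replace(params, convergence_distance=lower)


def load_stereo_params(path: str | os.PathLike) -> StereoParams:
    """Read stereo configuration from a JSON object keyed by the
    :class:`StereoParams` field names."""
    with open(os.fspath(path)) as fh:
        raw = json.load(fh)
    return StereoParams(**raw)
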