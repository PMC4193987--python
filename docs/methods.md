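# Methods

`anat3d` is a renderer-independent re-implementation of a
gesture-controlled stereoscopic anatomy workstation for the temporal
bone. It covers the full chain from CT volume to interactive 3D scene:
density segmentation, surface meshing, a skeleton-driven interaction
state machine, rigid-body scene integration, and off-axis stereo
mathematics. Everything runs on synthetic inputs — a CT phantom and
scripted skeleton streams — so the whole pipeline is testable without
scanner or sensor hardware.

## Volume model

Volumes are 3D Hounsfield-unit (HU) grids with node-centred samples:
voxel `(i, j, k)` sits at `origin + (i·sx, j·sy, k·sz)` mm. In memory
the index order is `(x, y, z)`; on disk the container's own axis
declaration governs and is transposed on load. HU are stored as signed
16-bit integers (the clinical range −1024…3071 fits) and widened in
memory. MetaImage (`.mhd`/`.raw`) and NRRD are read and written through
SimpleITK; a read-only DICOM series reader is included and flagged
experimental.

## Segmentation chain

The segmentation model is density windowing followed by membrane
repair, mirroring the clinical temporal-bone workflow:

* **Threshold presets.** An HU window with explicit inclusivity per
  bound. Shipped presets: `bone` = [382, 3071] HU inclusive (compact
  temporal bone), `membrane` = (−∞, −50) HU exclusive (the tympanic
  membrane is partly resolved below −50 HU), `soft_canal` = [−45, −15]
  (soft-tissue canal contents), `ossicle` = [1800, 3071] (dense
  ossicle bodies; nested inside the bone window), `air` = (−∞, −500].
  The one-sided membrane window necessarily admits air; the recovery
  recipe (`recover_structures`) subtracts the air window through the
  edit-mask mechanism — the reproducible surrogate for the expert who
  "adds or removes voxels" around the membrane margins.
* **Resampling.** Axis-wise rescaling onto a grid with the requested
  spacing and the same origin, covering the original extent; trilinear
  for HU, nearest-neighbour for labels (no label bleeding). Samples
  beyond the original extent take −1024 HU. Near-integer source
  coordinates are snapped (tolerance 1e-9, relative) so a sample landing
  exactly on the extent boundary is never pushed into background by
  round-off. The canonical use is re-slicing a 0.15 mm acquisition to a
  0.1 mm slice interval ahead of interpolation. Trilinear interpolation
  reproduces affine HU fields exactly (to 1e-6), which is the oracle the
  tests use.
* **Gap closing.** Morphological closing with a cubic
  (Chebyshev-ball) structuring element of half-width `r`, padded so
  border structures are not eroded. A cubic element is deliberate: a
  Euclidean ball of radius 1 cannot fill a single-voxel hole in a
  one-voxel sheet, because the hole's out-of-plane shadow is only
  covered by in-plane diagonal neighbours, which lie outside the
  Euclidean ball. The cube satisfies the intended contract (holes of
  diameter ≤ 2r in thin sheets are filled; radius 0 is the identity).
* **Thickening.** Thin sheets are grown until every through-sheet run
  is `min_t..max_t` voxels (defaults 2–3, the membrane-repair target so
  the membrane survives meshing). Each connected component's normal is
  estimated as its principal axis of least extent; runs along that axis
  grow symmetrically when the result stays within `max_t`, one-sided
  otherwise (and one-sided at volume borders). The estimator assumes
  sheet-like components — a dominant plane of support; for blobs or
  curves the chosen axis is a tie-break, and the operation remains
  extensive but the thickness contract only applies to sheets.
* **Composition.** Per-structure masks merge into a label map with ids
  1..n in list order; on overlap the later (more specific) mask wins.
  This resolves the deliberate nesting of the ossicle window inside the
  bone window.

## Meshing

Surfaces come from marching cubes on the binary field (level 0.5),
with a one-voxel background pad so every mesh is closed even at the
grid border; vertices are mapped to physical mm. Faces are wound
right-handed with outward normals (positive divergence-theorem
volume). STL is written in both dialects — binary as 80-byte header +
`uint32` count + 50 bytes per facet (little-endian, facet normals
recomputed from vertex order), ASCII in the standard grammar — and
read back with dialect auto-detection, exact-float32 vertex
deduplication, and an explicit error (expected vs actual byte count)
for truncated binaries. Mesh reports give counts, watertightness
(every undirected edge shared by exactly two triangles), surface area
and signed enclosed volume. No smoothing or decimation is applied.
STL carries no colour, so per-structure display colour lives in a
sidecar scene JSON.

## Phantom

The CT phantom emulates a 0.15 mm isotropic micro-CT acquisition of a
temporal bone in a 64³ grid (~9.6 mm field of view — a deliberately
small, fast stand-in; matrix size is a free parameter):

| structure | default HU | geometry |
|---|---|---|
| air background | −1000 | everywhere else |
| temporal bone | 1500 | slab with margins, z ∈ [10, 34) |
| soft canal ("facial nerve") | −30 | radius-6 tube through the slab |
| tympanic membrane | −70 | 1-voxel disk (r = 8) spanning the canal |
| ossicles | 2000 | two ellipsoids, semi-axes 5–8 voxels |

Ossicle semi-axes are at anatomical scale (bodies of ~1–2.5 mm, i.e.
5–17 voxels at 0.15 mm). Every default HU sits strictly inside its
recovery window and all values are pairwise distinct, so with zero
noise the threshold chain recovers the generating labels exactly
(Dice 1.0 per structure) — the pipeline's parameter-recovery
benchmark. Optional Gaussian HU noise is seeded and purely additive.
What the phantom does **not** emulate: beam hardening, partial-volume
blur, anatomically realistic cochlear geometry, or scanner-specific
noise texture. Passing tests therefore demonstrate that the operators
implement their contracts, not that the presets segment real scanner
data without expert editing.

Skeleton streams emulate 30 Hz Kinect-style tracking of the 20
first-generation joints, driven by scripted primitives (`idle`,
`hold_offset`, `recenter`, `tap_shoulder`, `exit_cube`,
`inject_mode`). Hands default to their control-cube centres; offsets
are expressed in cube units so controller tests are exact. Optional
seeded jitter models tracking noise and is off by default.

## Interaction model

Both hands are tracked relative to the **left** shoulder. Each hand
owns a control cube centred at a preset shoulder offset (defaults:
left (−0.05, −0.25, −0.35) m, right (0.41, −0.25, −0.35) m; half-width
0.15 m). The normalised offset `(hand − centre)/half_width` drives
motion: zero inside a spherical dead zone (0.15 of half-width),
linear beyond it (`v = gain · offset`), with full-scale gains of
0.5 scene-units/s (translation), 90°/s (rotation) and 20 units/s (the
selection sphere). The cube bounds the control range: a hand outside
the cube (any |component| > 1) contributes no motion; it only runs
the out-of-cube timer, and after 3 s (configurable — "several
seconds") motion is disabled until every tracked hand returns within
the recentre radius (0.15). Without that suppression rule a shoulder
tap, which parks the right hand far outside its cube, would slew the
camera mid-gesture.

Mode switching uses a left-shoulder tap by the right hand: strictly
inside 0.15 m for ≥ 0.1 s, debounced (the hand must leave the radius
before re-arming, one event per entry). A `mode_change` event on a
stream frame — the stand-in for a voice command, since speech
recognition is out of scope — triggers the same edge. The mode graph
is `NAVIGATE → SELECT → MANIPULATE → NAVIGATE`: navigation maps the
left hand to camera translation and the right to camera rotation;
selection steers a picking sphere that highlights the nearest object
centroid (ties break to the lowest id); a tap with a highlight selects
the object, whose pose the hands then drive alone; a further tap
deselects. A tap in SELECT with nothing highlighted is a no-op.

## Scene and integration

Right-handed coordinates, scene units mm, camera looking down its
body-frame −z with y up. Velocities are body-frame (egocentric camera
flight). Pose integration is the exact flow of the constant body
twist: `q ← q·exp(ω dt)` and `p ← p + R(q)·J(ω dt)·v·dt` with `J` the
SO(3) left Jacobian, renormalising the quaternion each step — so two
half-steps compose exactly to one full step and quaternion norms stay
within 1e-9 over ≥ 10⁵ steps. Replay feeds every stream frame through
the controller, applies the commands with dt from consecutive
timestamps (strictly increasing, or an error), and logs every pose,
mode and command per frame as deterministic line-delimited JSON.
Meshes are never mutated; only poses change.

## Stereo

Off-axis (parallel-axis, asymmetric-frustum) stereo: eyes at
±e/2 along the camera x axis with `e = eye_separation · depth_gain`,
both frusta sharing the convergence plane, which is mapped 1:1 onto
the physical screen. Screen parallax is `p(z) = e(1 − C/z)` mm: zero
at the convergence distance C, negative (pop-out) nearer, approaching
e from below at infinity. The closed form and the projected
left/right difference agree to 1e-9 — the module's dual-path
invariant. Divergence is audited against the viewer's interocular
distance (default 65 mm): fusion fails when positive parallax reaches
it. `popout_adjust` raises C to `object_depth · 1.1` (margin 0.1), or
further if the scene's far extent demands it, while capping C so the
crossed parallax at the object stays under the same limit; when the
two bounds cross, the adjustment reports infeasibility naming the
binding constraint. Toed-in cameras are deliberately avoided
(vertical parallax). The vendor-style "depth"/"convergence" knobs map
to `depth_gain` and `convergence_distance`; this is a geometric model
of those controls, not a driver-level emulation.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at 64³ voxels,
sessions of a few hundred 30 Hz frames, and stereo samples of a few
hundred points — sizes chosen so the full chain stays exact and
auditable. Tolerances: 1e-6 for affine-resampling and closed-form
rotation checks, 1e-9 for quaternion norms and stereo dual-path
agreement, 5 % for marching-cubes volume against the generating solid
(the membrane is meshed after thickening; a one-voxel sheet is exactly
what the thickening step exists to repair). Degenerate inputs are
errors, not silent repairs: empty masks cannot be meshed, misaligned
grids cannot be combined, out-of-order frames stop a replay.

## Known limitations

No automated (atlas- or learning-based) segmentation; no mesh
smoothing or decimation; no live sensor acquisition, speech
recognition, GPU rendering or shutter-glass synchronisation. The
expert-editing step is modelled as explicit edit masks, which makes it
reproducible but places the burden of anatomical judgement on the
inputs.
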