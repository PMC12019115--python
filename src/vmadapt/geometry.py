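"""Task-space geometry for cursor- and camera-controlled aiming.

Three input-to-screen mappings are supported:

* **Point** — device displacements translate a cursor over a static scene
  (ordinary desktop cursor control).
* **Look** — device displacements pan/tilt a camera; the cursor stays fixed
  at the screen centre and the scene moves in the opposite direction
  (first-person-shooter style aiming).
* **Inverted Look** — Look with the input-to-camera gain negated on one or
  both axes, so e.g. a forward hand movement pans the view down.

The contexts are *equated*: for any input stream the cursor's position
relative to the task plane (and hence the cursor-to-target vector) is
identical across contexts. The camera realises this by mapping each axis
independently through the pinhole relation ``s = d * tan(angle)``, where
``d`` is the perpendicular distance from the camera to the task plane, so a
pan/tilt acts as an exact rigid screen translation of the plane.

All positions are in arbitrary workspace units ("au"; the screen height
spans 4 au and the target ring has a 2 au diameter). Screen y increases
upward; angles are measured counter-clockwise from the +x axis, so the four
cardinal targets 0/90/180/270 degrees sit right/up/left/down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Context",
    "Rotation",
    "TaskLayout",
    "ContextConfig",
    "GeometryOverflowError",
    "ForwardMapResult",
    "wrap_angle",
    "rotation_matrix",
    "apply_rotation",
    "forward_map",
    "invert_map",
    "snap_to_start",
]

POINT = "point"
LOOK = "look"
INVERTED_LOOK = "inverted_look"
CONTEXTS = (POINT, LOOK, INVERTED_LOOK)

# Inverted-Look axis conventions
INVERTED_BOTH = "both"
INVERTED_VERTICAL_ONLY = "vertical_only"


class Context:
    """Namespace of valid context names."""

    POINT = POINT
    LOOK = LOOK
    INVERTED_LOOK = INVERTED_LOOK


class GeometryOverflowError(RuntimeError):
    """Camera pose left the representable range (|angle| >= 90 deg)."""


def wrap_angle(angle):
    """Wrap an angle in degrees into the half-open interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(((-a + 180.0) % 360.0) - 180.0)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Rotation:
    """A visuomotor rotation of fixed magnitude and direction.

    ``direction`` is ``"cw"``, ``"ccw"`` or ``"none"``; the magnitude must be
    zero iff the direction is ``"none"``. The signed convention is
    counter-clockwise positive.
    """

    magnitude: float = 0.0
    direction: str = "none"

    def __post_init__(self):
        if self.direction not in ("cw", "ccw", "none"):
            raise ValueError(f"unknown rotation direction {self.direction!r}")
        if (self.magnitude == 0.0) != (self.direction == "none"):
            raise ValueError("rotation magnitude must be 0 iff direction is 'none'")
        if self.magnitude < 0:
            raise ValueError("rotation magnitude must be non-negative")

    @property
    def signed_deg(self) -> float:
        if self.direction == "ccw":
            return float(self.magnitude)
        if self.direction == "cw":
            return -float(self.magnitude)
        return 0.0

    @classmethod
    def from_signed(cls, deg: float) -> "Rotation":
        if deg == 0:
            return cls(0.0, "none")
        return cls(abs(float(deg)), "ccw" if deg > 0 else "cw")


@dataclass(frozen=True)
class TaskLayout:
    """Workspace geometry (all sizes in au)."""

    start_point_diameter: float = 0.1
    target_diameter: float = 0.2
    target_ring_diameter: float = 2.0
    target_plane_diameter: float = 3.0
    cursor_diameter: float = 0.15
    snap_radius: float = 0.05
    target_angles: tuple = (0.0, 90.0, 180.0, 270.0)

    def __post_init__(self):
        for name in (
            "start_point_diameter",
            "target_diameter",
            "target_ring_diameter",
            "target_plane_diameter",
            "cursor_diameter",
            "snap_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def target_radius(self) -> float:
        return self.target_ring_diameter / 2.0

    def target_position(self, angle_deg: float) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        return self.target_radius * np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class ContextConfig:
    """How device input maps to the screen.

    ``camera_distance`` is the perpendicular distance (au) from the camera to
    the task plane; the default of 10 au keeps camera angles below ~9 deg
    over the 2 au workspace, i.e. well inside the small-angle regime.
    ``inverted_axes`` is only consulted for the Inverted-Look context.
    """

    context: str = POINT
    camera_distance: float = 10.0
    inverted_axes: str = INVERTED_BOTH

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.camera_distance <= 0:
            raise ValueError("camera_distance must be positive")
        if self.inverted_axes not in (INVERTED_BOTH, INVERTED_VERTICAL_ONLY):
            raise ValueError(f"unknown inverted_axes {self.inverted_axes!r}")


def rotation_matrix(deg: float) -> np.ndarray:
    """2x2 counter-clockwise rotation matrix."""
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def apply_rotation(delta, rot: Rotation):
    """Rotate a vector (or (N, 2) array of vectors) about the origin.

    Norm-preserving; a zero-magnitude rotation returns the input unchanged.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta must be finite")
    if rot.signed_deg == 0.0:
        return delta.copy()
    return delta @ rotation_matrix(rot.signed_deg).T


def _invert_input(deltas: np.ndarray, inverted_axes: str) -> np.ndarray:
    out = deltas.copy()
    if inverted_axes == INVERTED_BOTH:
        out *= -1.0
    else:  # vertical_only
        out[..., 1] *= -1.0
    return out


@dataclass
class ForwardMapResult:
    """Per-sample screen state produced by :func:`forward_map`.

    All paths have shape (N+1, 2) for N input deltas and start at the
    start-point (origin). ``cursor_plane`` is the cursor position expressed
    in task-plane coordinates — the quantity that is identical across
    contexts by construction.
    """

    cursor_screen: np.ndarray
    scene_offset: np.ndarray
    cursor_plane: np.ndarray
    pose_deg: np.ndarray = field(default=None)  # (N+1, 2) yaw, pitch


def forward_map(input_deltas, cfg: ContextConfig, rot: Rotation) -> ForwardMapResult:
    """Map a stream of device input deltas to screen/scene trajectories.

    Point: the cursor accumulates the rotated deltas over a static scene.
    Look: the cursor stays at the screen centre and the camera pans/tilts so
    that the task plane translates by exactly the negated Point cursor path.
    Inverted Look: as Look, with the input negated on the configured axes
    before the camera update. The visuomotor rotation is applied to the
    cursor (Point) or to the camera update (Look variants).
    """
    deltas = np.atleast_2d(np.asarray(input_deltas, dtype=float))
    if deltas.size == 0:
        deltas = deltas.reshape(0, 2)
    if deltas.shape[-1] != 2:
        raise ValueError("input deltas must have shape (N, 2)")
    if not np.all(np.isfinite(deltas)):
        raise ValueError("input deltas must be finite")

    if cfg.context == INVERTED_LOOK:
        deltas = _invert_input(deltas, cfg.inverted_axes)

    rotated = apply_rotation(deltas, rot)
    plane = np.vstack([np.zeros((1, 2)), np.cumsum(rotated, axis=0)])

    if cfg.context == POINT:
        return ForwardMapResult(
            cursor_screen=plane.copy(),
            scene_offset=np.zeros_like(plane),
            cursor_plane=plane,
            pose_deg=np.zeros_like(plane),
        )

    pose = np.rad2deg(np.arctan(plane / cfg.camera_distance))
    if not np.all(np.isfinite(pose)) or np.any(np.abs(pose) >= 90.0):
        raise GeometryOverflowError("camera pose outside (-90, 90) degrees")
    return ForwardMapResult(
        cursor_screen=np.zeros_like(plane),
        scene_offset=-plane,
        cursor_plane=plane,
        pose_deg=pose,
    )


def invert_map(desired_cursor_path, cfg: ContextConfig, rot: Rotation) -> np.ndarray:
    """Input deltas that realise a desired task-plane cursor path.

    ``desired_cursor_path`` is an (M, 2) array of absolute cursor positions
    in task-plane coordinates starting at the start-point (origin). Returns
    (M-1, 2) device input deltas such that ``forward_map`` reproduces the
    path exactly (two-sided inverse within floating-point precision).
    """
    path = np.atleast_2d(np.asarray(desired_cursor_path, dtype=float))
    if path.shape[0] < 1 or path.shape[-1] != 2:
        raise ValueError("desired path must have shape (M, 2)")
    if np.linalg.norm(path[0]) > 1e-12:
        raise ValueError("desired path must start at the start-point")
    plane_deltas = np.diff(path, axis=0)
    inv_rot = Rotation.from_signed(-rot.signed_deg)
    deltas = apply_rotation(plane_deltas, inv_rot)
    if cfg.context == INVERTED_LOOK:
        deltas = _invert_input(deltas, cfg.inverted_axes)
    return deltas


def snap_to_start(cursor, layout: TaskLayout = TaskLayout()) -> np.ndarray:
    """Snap the homing cursor to the start-point when strictly inside the
    snap radius (0.05 au); positions at or beyond the radius are unchanged."""
    cursor = np.asarray(cursor, dtype=float)
    if np.linalg.norm(cursor) < layout.snap_radius:
        return np.zeros(2)
    return cursor.copy()
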