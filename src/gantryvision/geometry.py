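"""Camera geometry: world -> camera -> image transform chain and its inverse.

The net transform maps a plant's world-frame coordinates to its position in
a captured image.  It factors into a rigid world-to-camera transform
(translation to the optical center followed by pan and tilt rotations) and
a rectilinear (pinhole) camera-to-image projection.  Because plants sit on
the floor — their z coordinate is known — the chain is invertible: an image
point back-projects along its ray to a unique point on the ground plane.

Conventions
-----------
* World frame: millimeters, origin at the base corner of the gantry's first
  column, z up.
* Camera frame: origin at the optical center, x forward along the optical
  axis, y left, z up.
* pan = 0 points the optical axis along world +x; positive pan rotates
  counterclockwise (toward +y) about the vertical axis.
* tilt is measured from the horizontal, positive downward; the physical
  head covers the full 180 degree span tilt in [-90, +90].
* Image frame: fractional coordinates, origin top-left, u rightward,
  v downward, (0.5, 0.5) on the optical axis.

A plant is replaced, for box computation, by a bounding sphere large enough
to contain it; the sphere's silhouette cone (half-angle asin(R/D) at
camera distance D) is projected to a bounding box guaranteed to contain
the whole plant's image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import TravelVolume

__all__ = [
    "WorldPoint",
    "CameraPose",
    "CameraModel",
    "CameraFramePoint",
    "BoundingSphere",
    "ImageBox",
    "GeometryError",
    "PointBehindCameraError",
    "CameraInsideSphereError",
    "NoGroundIntersectionError",
    "EmptyPoseSetError",
    "world_to_camera",
    "camera_to_image",
    "project_sphere",
    "image_to_ground",
    "generate_pose_set",
    "aim_at",
]


class GeometryError(ValueError):
    """Base class for geometric preconditions being violated."""


class PointBehindCameraError(GeometryError):
    """The point lies on or behind the image plane (x_f <= 0)."""


class CameraInsideSphereError(GeometryError):
    """The optical center lies inside (or on) the bounding sphere."""


class NoGroundIntersectionError(GeometryError):
    """The back-projected ray does not hit the ground plane in front of the camera."""


class EmptyPoseSetError(GeometryError):
    """No candidate camera pose survived the travel-volume filter."""


@dataclass(frozen=True)
class WorldPoint:
    """A point in the gantry world frame (millimeters, z up)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise GeometryError("WorldPoint coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def in_volume(self, volume: TravelVolume, tol: float = 1e-9) -> bool:
        return volume.contains(self.x, self.y, self.z, tol=tol)


@dataclass(frozen=True)
class CameraFramePoint:
    """A point in the camera frame: x_f forward, y_f left, z_f up (mm)."""

    x_f: float
    y_f: float
    z_f: float

    @property
    def visible(self) -> bool:
        return self.x_f > 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x_f, self.y_f, self.z_f], dtype=float)


@dataclass(frozen=True)
class CameraPose:
    """Extrinsic state: optical-center position plus pan/tilt (degrees)."""

    position: WorldPoint
    pan: float = 0.0
    tilt: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pan", self.pan % 360.0)
        if not -90.0 <= self.tilt <= 90.0:
            raise GeometryError(f"tilt {self.tilt} outside [-90, 90] degrees")

    def rotation_world_to_camera(self) -> np.ndarray:
        """3x3 matrix whose rows are the camera's forward/left/up axes in world coords."""
        p = math.radians(self.pan)
        t = math.radians(self.tilt)
        cp, sp, ct, st = math.cos(p), math.sin(p), math.cos(t), math.sin(t)
        forward = np.array([ct * cp, ct * sp, -st])
        left = np.array([-sp, cp, 0.0])
        up = np.array([st * cp, st * sp, ct])
        return np.vstack([forward, left, up])


@dataclass(frozen=True)
class CameraModel:
    """Intrinsic state: resolution and diagonal field of view, rectilinear."""

    width: int = 4000
    height: int = 3000
    fov_diagonal_deg: float = 98.7
    projection: str = "rectilinear"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("resolution must be positive")
        if not 0.0 < self.fov_diagonal_deg < 180.0:
            raise GeometryError("diagonal FOV must be in (0, 180) degrees")
        if self.projection != "rectilinear":
            raise GeometryError(f"unsupported projection {self.projection!r}")

    @property
    def focal_px(self) -> float:
        """Focal length in pixels, derived from the diagonal FOV and pixel diagonal."""
        diag = math.hypot(self.width, self.height)
        return (diag / 2.0) / math.tan(math.radians(self.fov_diagonal_deg) / 2.0)

    @property
    def fov_horizontal_deg(self) -> float:
        return 2.0 * math.degrees(math.atan((self.width / 2.0) / self.focal_px))

    @property
    def fov_vertical_deg(self) -> float:
        return 2.0 * math.degrees(math.atan((self.height / 2.0) / self.focal_px))


@dataclass(frozen=True)
class BoundingSphere:
    """Sphere replacing a plant for box computation."""

    center: WorldPoint
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise GeometryError("sphere radius must be >= 0")


@dataclass(frozen=True)
class ImageBox:
    """Axis-aligned fractional box, origin top-left, u rightward, v downward."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_min <= self.x_max <= 1.0):
            raise GeometryError("x bounds must satisfy 0 <= x_min <= x_max <= 1")
        if not (0.0 <= self.y_min <= self.y_max <= 1.0):
            raise GeometryError("y bounds must satisfy 0 <= y_min <= y_max <= 1")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def intersection_area(self, other: "ImageBox") -> float:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return max(w, 0.0) * max(h, 0.0)


def world_to_camera(pose: CameraPose, p: WorldPoint) -> CameraFramePoint:
    """Rigid transform of ``p`` into the camera frame of ``pose``.

    Translation by the negated optical-center position, then the inverse pan
    rotation about the vertical axis, then the inverse tilt rotation about
    the camera's transverse (left) axis.  Distance-preserving.
    """
    R = pose.rotation_world_to_camera()
    q = R @ (p.as_array() - pose.position.as_array())
    return CameraFramePoint(*q)


def _project_direction(model: CameraModel, d: np.ndarray) -> tuple[float, float]:
    """Rectilinear projection of a camera-frame direction to (u, v) fractions.

    Directions with non-positive forward component map to +-inf so callers
    that clamp (sphere boxes) degrade gracefully at the frame edge.
    """
    f = model.focal_px
    if d[0] <= 0.0:
        u = math.inf if -d[1] > 0 else (-math.inf if -d[1] < 0 else 0.5)
        v = math.inf if -d[2] > 0 else (-math.inf if -d[2] < 0 else 0.5)
        return u, v
    u = 0.5 + f * (-d[1] / d[0]) / model.width
    v = 0.5 + f * (-d[2] / d[0]) / model.height
    return u, v


def camera_to_image(model: CameraModel, q: CameraFramePoint) -> tuple[float, float]:
    """Project a visible camera-frame point to fractional image coordinates.

    The optical axis maps to (0.5, 0.5); a ray at half the horizontal FOV
    maps to the left/right image border.

    Raises
    ------
    PointBehindCameraError
        If ``q.x_f <= 0``.
    """
    if q.x_f <= 0.0:
        raise PointBehindCameraError(f"point at x_f={q.x_f} is not in front of the camera")
    return _project_direction(model, q.as_array())


def _tangent_extreme_dirs(a: np.ndarray, b1: np.ndarray, b2: np.ndarray, comp: int) -> list[np.ndarray]:
    """Directions on the silhouette-cone boundary extremizing one image axis.

    The cone boundary is d(theta) = a + b1 cos(theta) + b2 sin(theta); the
    stationarity condition of -d[comp]/d[0] reduces to
    A sin(theta) + B cos(theta) + K = 0, solved in closed form.
    """
    A = a[comp] * b1[0] - a[0] * b1[comp]
    B = a[0] * b2[comp] - a[comp] * b2[0]
    K = b2[comp] * b1[0] - b1[comp] * b2[0]
    r = math.hypot(A, B)
    thetas: list[float] = []
    if r > 0 and abs(K) <= r:
        phi = math.atan2(B, A)
        base = math.asin(max(-1.0, min(1.0, -K / r)))
        thetas = [base - phi, math.pi - base - phi]
    # axis-aligned fallbacks cost nothing and guard degenerate geometry
    thetas += [0.0, math.pi / 2.0, math.pi, 3.0 * math.pi / 2.0]
    return [a + b1 * math.cos(t) + b2 * math.sin(t) for t in thetas]


def project_sphere(pose: CameraPose, model: CameraModel, s: BoundingSphere) -> ImageBox | None:
    """Fractional box containing the full projection of a bounding sphere.

    Extreme rays of the silhouette cone (half-angle ``asin(R/D)``) are found
    in closed form for each image axis, projected, and min/maxed; the box is
    clamped to [0, 1].  Returns ``None`` when the clamped box is empty
    (sphere entirely outside the frame).

    Raises
    ------
    PointBehindCameraError
        If the sphere center is not visible.
    CameraInsideSphereError
        If the camera-to-center distance D <= R.
    """
    q = world_to_camera(pose, s.center)
    if q.x_f <= 0.0:
        raise PointBehindCameraError("sphere center is not in front of the camera")
    qv = q.as_array()
    D = float(np.linalg.norm(qv))
    if D <= s.radius:
        raise CameraInsideSphereError(f"camera at distance {D:.3f} inside sphere of radius {s.radius:.3f}")
    if s.radius == 0.0:
        u, v = camera_to_image(model, q)
        if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
            return None
        return ImageBox(u, u, v, v)

    alpha = math.asin(s.radius / D)
    c = qv / D
    # orthonormal basis of the plane perpendicular to the center ray; the
    # first axis follows image-x (camera -y) where possible
    ex = np.array([0.0, -1.0, 0.0])
    exp_ = ex - np.dot(ex, c) * c
    nx = float(np.linalg.norm(exp_))
    if nx < 1e-12:  # center ray parallel to image-x: any perpendicular pair works
        helper = np.array([1.0, 0.0, 0.0]) if abs(c[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
        exp_ = np.cross(c, helper)
        exp_ /= np.linalg.norm(exp_)
    else:
        exp_ /= nx
    eyp = np.cross(c, exp_)

    a = c * math.cos(alpha)
    b1 = exp_ * math.sin(alpha)
    b2 = eyp * math.sin(alpha)
    dirs = _tangent_extreme_dirs(a, b1, b2, comp=1) + _tangent_extreme_dirs(a, b1, b2, comp=2)
    us, vs = zip(*(_project_direction(model, d) for d in dirs))
    x_min, x_max = max(0.0, min(us)), min(1.0, max(us))
    y_min, y_max = max(0.0, min(vs)), min(1.0, max(vs))
    if x_min > x_max or y_min > y_max:
        return None
    return ImageBox(x_min, x_max, y_min, y_max)


def image_to_ground(
    pose: CameraPose,
    model: CameraModel,
    u: float,
    v: float,
    ground_z: float = 0.0,
) -> WorldPoint:
    """Back-project an image point onto the horizontal plane z = ``ground_z``.

    Exact inverse of the forward chain for points on that plane.

    Raises
    ------
    NoGroundIntersectionError
        If the ray is parallel to the plane or points away from it.
    """
    f = model.focal_px
    d_cam = np.array([1.0, -(u - 0.5) * model.width / f, -(v - 0.5) * model.height / f])
    R = pose.rotation_world_to_camera()
    d_world = R.T @ d_cam
    pz = pose.position.z
    if abs(d_world[2]) < 1e-15:
        raise NoGroundIntersectionError("ray is parallel to the ground plane")
    t = (ground_z - pz) / d_world[2]
    if t <= 0.0:
        raise NoGroundIntersectionError("ground plane lies behind the camera along this ray")
    p = pose.position.as_array() + t * d_world
    return WorldPoint(p[0], p[1], float(ground_z))


def aim_at(position: WorldPoint, target: WorldPoint) -> CameraPose:
    """Pose at ``position`` whose optical axis passes through ``target``."""
    d = target.as_array() - position.as_array()
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise GeometryError("cannot aim a camera at its own position")
    pan = math.degrees(math.atan2(d[1], d[0])) % 360.0
    tilt = math.degrees(math.asin(max(-1.0, min(1.0, -d[2] / norm))))
    return CameraPose(position=position, pan=pan, tilt=tilt)


def generate_pose_set(
    target: WorldPoint,
    position_class: str,
    rings: Sequence[tuple[float, float, int]],
    volume: TravelVolume | None = None,
) -> list[CameraPose]:
    """Camera poses on horizontal circles around a target, all aimed at it.

    Each ring is ``(height, radius, count)``: ``count`` optical-center
    positions evenly spaced on the circle of that radius at world height
    ``height`` (mm), centered above the target.  Interior targets get full
    circles; edge targets — those at the border of the travel volume — get
    only the half-range of azimuths facing into the volume (half a cylinder
    of viewpoints).  Candidates outside the travel volume are dropped.

    Raises
    ------
    EmptyPoseSetError
        If no candidate survives the volume filter.
    GeometryError
        On an unknown position class or empty/invalid rings.
    """
    if position_class not in ("edge", "interior"):
        raise GeometryError(f"unknown position class {position_class!r}")
    if not rings:
        raise GeometryError("rings must be non-empty")
    vol = volume if volume is not None else TravelVolume()
    # inward normal of the nearest vertical boundary face: the half-cylinder
    # of viewpoints for an edge target faces away from that boundary
    face_normals = {
        target.x: (1.0, 0.0),
        vol.x_size - target.x: (-1.0, 0.0),
        target.y: (0.0, 1.0),
        vol.y_size - target.y: (0.0, -1.0),
    }
    nx_, ny_ = face_normals[min(face_normals)]
    inward = math.atan2(ny_, nx_)

    poses: list[CameraPose] = []
    for height, radius, count in rings:
        if count <= 0:
            raise GeometryError("ring count must be > 0")
        if position_class == "interior":
            azimuths = [2.0 * math.pi * i / count for i in range(count)]
        else:
            # half-range facing into the volume, endpoints kept off the border
            azimuths = [inward - math.pi / 2.0 + math.pi * (i + 0.5) / count for i in range(count)]
        for az in azimuths:
            pos = WorldPoint(
                target.x + radius * math.cos(az),
                target.y + radius * math.sin(az),
                height,
            )
            if not pos.in_volume(vol):
                continue
            poses.append(aim_at(pos, target))
    if not poses:
        raise EmptyPoseSetError("no candidate pose lies inside the travel volume")
    return poses


def filter_margin(boxes: Iterable[ImageBox | None], margin: float) -> list[ImageBox | None]:
    """Replace boxes touching the outer ``margin`` fraction of the frame with None.

    Stands in for lens-distortion correction: distortion concentrates at the
    frame margins, so boxes reaching into them are discarded.
    """
    if margin <= 0.0:
        return list(boxes)
    out: list[ImageBox | None] = []
    for b in boxes:
        if b is None:
            out.append(None)
        elif b.x_min < margin or b.y_min < margin or b.x_max > 1.0 - margin or b.y_max > 1.0 - margin:
            out.append(None)
        else:
            out.append(b)
    return out
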