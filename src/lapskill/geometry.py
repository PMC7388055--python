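"""3D primitives of the virtual workspace and exact distance/containment queries.

All coordinates are millimetres in a right-handed frame: origin at the centre
of the sensor pad, +y up, +z toward the user.  Shapes are closed sets, so
boundary contact counts as containment/contact.  Scalar entry points accept
anything convertible to a length-3 float vector; the ``*_many`` variants are
vectorised over an ``(n, 3)`` array of query points and are what the event
detector uses on whole trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "Point3",
    "Segment3",
    "Sphere",
    "Cylinder",
    "Cuboid",
    "Polyline3",
    "Shape",
    "as_point",
    "polyline_length",
    "distance_point_to_segment",
    "distance_points_to_polyline",
    "distance_point_to_polyline",
    "distance_segment_segment",
    "segment_pairs_distance",
    "contains",
    "surface_distance",
]

Point3 = np.ndarray  # shape (3,), float64, finite


def as_point(p: Iterable[float]) -> Point3:
    """Coerce to a finite (3,) float vector; raise ValueError otherwise."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"point must have 3 coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point coordinates must be finite, got {arr}")
    return arr


def _as_points(pts) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Segment3:
    """Directed line segment; models the intracorporeal instrument shaft."""

    a: Point3
    b: Point3

    def __post_init__(self):
        object.__setattr__(self, "a", as_point(self.a))
        object.__setattr__(self, "b", as_point(self.b))
        if np.array_equal(self.a, self.b):
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))


@dataclass(frozen=True)
class Sphere:
    center: Point3
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        if not (self.radius > 0):
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder between two axis endpoints; ``hollow`` marks containers
    whose wall (not interior) is the contact surface."""

    axis_a: Point3
    axis_b: Point3
    radius: float
    hollow: bool = False

    def __post_init__(self):
        object.__setattr__(self, "axis_a", as_point(self.axis_a))
        object.__setattr__(self, "axis_b", as_point(self.axis_b))
        if np.array_equal(self.axis_a, self.axis_b):
            raise ValueError("degenerate cylinder: axis endpoints coincide")
        if not (self.radius > 0):
            raise ValueError(f"cylinder radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Cuboid:
    min_corner: Point3
    max_corner: Point3

    def __post_init__(self):
        object.__setattr__(self, "min_corner", as_point(self.min_corner))
        object.__setattr__(self, "max_corner", as_point(self.max_corner))
        if not np.all(self.min_corner < self.max_corner):
            raise ValueError("cuboid requires min_corner < max_corner componentwise")

    @property
    def center(self) -> Point3:
        return 0.5 * (self.min_corner + self.max_corner)


@dataclass(frozen=True)
class Polyline3:
    """Ordered open polyline; houses the ideal path of a task."""

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = _as_points(self.vertices)
        if arr.shape[0] < 2:
            raise ValueError("polyline needs at least 2 vertices")
        if np.any(np.all(np.diff(arr, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive polyline vertices must be distinct")
        if not np.all(np.isfinite(arr)):
            raise ValueError("polyline vertices must be finite")
        object.__setattr__(self, "vertices", arr)

    def __len__(self) -> int:
        return self.vertices.shape[0]


Shape = Union[Sphere, Cylinder, Cuboid]


def polyline_length(p: Polyline3) -> float:
    """Total Euclidean arc length of the polyline, in mm."""
    return float(np.linalg.norm(np.diff(p.vertices, axis=0), axis=1).sum())


def distance_point_to_segment(q, a, b) -> float:
    q, a, b = as_point(q), as_point(a), as_point(b)
    return float(_points_to_segment(q[None, :], a, b)[0])


def _points_to_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from (n,3) points to segment ab; handles a == b."""
    d = b - a
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ d / denom, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


def distance_points_to_polyline(pts, p: Polyline3) -> np.ndarray:
    """Minimum distance from each of (n,3) points to the polyline."""
    pts = _as_points(pts)
    v = p.vertices
    best = np.full(pts.shape[0], np.inf)
    for i in range(v.shape[0] - 1):
        np.minimum(best, _points_to_segment(pts, v[i], v[i + 1]), out=best)
    return best


def distance_point_to_polyline(q, p: Polyline3) -> float:
    return float(distance_points_to_polyline(as_point(q)[None, :], p)[0])


def distance_segment_segment(s1: Segment3, s2: Segment3) -> float:
    d = segment_pairs_distance(
        s1.a[None, :], s1.b[None, :], s2.a[None, :], s2.b[None, :]
    )
    return float(d[0])


def segment_pairs_distance(p1, q1, p2, q2) -> np.ndarray:
    """Minimum distance between paired segments p1[i]q1[i] and p2[i]q2[i].

    Vectorised closed-form solution (clamped quadratic minimisation); the
    degenerate parallel case falls back to endpoint/segment distances.
    """
    p1, q1, p2, q2 = (_as_points(x) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-12 * a * e + 1e-300, (b * f - c * e) / denom, 0.0)
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(e > 0, (b * s + f) / e, 0.0)
    # re-clamp s against the clamped t, then recompute closest points
    t_cl = np.clip(t, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(a > 0, np.clip((b * t_cl - c) / np.where(a > 0, a, 1.0), 0.0, 1.0), 0.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t_cl[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def _sphere_signed(pts: np.ndarray, s: Sphere) -> np.ndarray:
    return np.linalg.norm(pts - s.center, axis=1) - s.radius


def _cylinder_axial_radial(pts: np.ndarray, c: Cylinder):
    axis = c.axis_b - c.axis_a
    h = float(np.linalg.norm(axis))
    u = axis / h
    rel = pts - c.axis_a
    axial = rel @ u
    radial = np.linalg.norm(rel - axial[:, None] * u, axis=1)
    return axial, radial, h


def contains(shape: Shape, q) -> bool:
    """True iff q lies inside or on the boundary of the (closed) shape.

    A hollow cylinder contains a point when it is within the radius of the
    axis and between the planes of the axis endpoints, i.e. hollowness does
    not change containment — it changes which surface counts as contact.
    """
    return bool(contains_many(shape, as_point(q)[None, :])[0])


def contains_many(shape: Shape, pts) -> np.ndarray:
    pts = _as_points(pts)
    if isinstance(shape, Sphere):
        return _sphere_signed(pts, shape) <= 0.0
    if isinstance(shape, Cuboid):
        return np.all(
            (pts >= shape.min_corner) & (pts <= shape.max_corner), axis=1
        )
    if isinstance(shape, Cylinder):
        axial, radial, h = _cylinder_axial_radial(pts, shape)
        return (axial >= 0.0) & (axial <= h) & (radial <= shape.radius)
    raise TypeError(f"unsupported shape: {type(shape).__name__}")


def surface_distance(shape: Shape, pts) -> np.ndarray:
    """Unsigned distance from each point to the shape's contact surface.

    For solid spheres/cylinders/cuboids this is distance to the boundary
    surface (zero on the surface, positive inside and outside alike); for a
    hollow cylinder it is the distance to the cylindrical wall only, which is
    what "contact with the container margins" means for a containment task.
    """
    pts = _as_points(pts)
    if isinstance(shape, Sphere):
        return np.abs(_sphere_signed(pts, shape))
    if isinstance(shape, Cuboid):
        lo = shape.min_corner - pts
        hi = pts - shape.max_corner
        out = np.maximum(np.maximum(lo, hi), 0.0)
        d_out = np.linalg.norm(out, axis=1)
        d_in = np.min(np.minimum(pts - shape.min_corner, shape.max_corner - pts), axis=1)
        inside = np.all((pts >= shape.min_corner) & (pts <= shape.max_corner), axis=1)
        return np.where(inside, d_in, d_out)
    if isinstance(shape, Cylinder):
        axial, radial, h = _cylinder_axial_radial(pts, shape)
        if shape.hollow:
            # wall only: an annular band at distance `radius` from the axis
            dr = np.abs(radial - shape.radius)
            da = np.maximum(np.maximum(-axial, axial - h), 0.0)
            return np.hypot(dr, da)
        dr = radial - shape.radius
        da = np.maximum(-axial, axial - h)
        outside = np.hypot(np.maximum(dr, 0.0), np.maximum(da, 0.0))
        inside_depth = np.minimum(-dr, -da)
        return np.where((dr <= 0) & (da <= 0), inside_depth, outside)
    raise TypeError(f"unsupported shape: {type(shape).__name__}")
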