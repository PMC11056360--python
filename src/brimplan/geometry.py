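"""3-D geometric primitives for brim morphometry.

Everything here is plain computation on points in a right-handed frame with
units of millimetres.  The cranial direction of the body ("major axis") is by
convention +z unless a model carries its own axis.  Curves such as the pelvic
brim are represented as ordered polylines parameterized by cumulative chord
length ("arc position"), which is the metric all zone lengths are reported in.

Absolute tolerances are used throughout: the anatomy of interest lives at the
1e2 mm scale, so a fixed 1e-9 mm epsilon is far below measurement precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    GeometryError,
    NoIntersectionError,
)

#: Global cranial (head-ward) direction used to orient fitted normals.
CRANIAL_AXIS = np.array([0.0, 0.0, 1.0])

_ON_PLANE_TOL = 1e-9     # mm; a vertex closer than this lies "on" a plane
_MIN_VERTEX_SEP = 1e-9   # mm; consecutive polyline vertices must be farther apart
_TIE_TOL = 1e-12         # mm; distance ties in nearest-point queries


def _as_points(points, min_count: int, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"{what}: expected an (n, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise GeometryError(f"{what}: coordinates must be finite")
    if len(pts) < min_count:
        raise DegenerateInputError(f"{what}: need at least {min_count} points, got {len(pts)}")
    return pts


def _unit(v, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise GeometryError(f"{what} has zero length")
    return v / n


def _orient_normal(n: np.ndarray) -> np.ndarray:
    """Fix the sign of a unit normal: non-negative cranial (+z) component,
    ties broken toward +x, then +y."""
    for idx in (2, 0, 1):  # z, then x, then y
        if abs(n[idx]) > 1e-12:
            return n if n[idx] > 0 else -n
    return n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            n = _unit(n, "plane normal")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


@dataclass(frozen=True)
class Circle3D:
    """A circle embedded in 3-D: center, radius and the unit normal of its plane."""

    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, "circle normal"))
        if not self.radius > 0:
            raise GeometryError(f"circle radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Polyline3:
    """An ordered 3-D polyline with cumulative chord-length parameterization.

    ``arc_positions[i]`` is the distance in mm from vertex 0 to vertex i along
    the polygon; vertex 0 sits at arc position 0.
    """

    vertices: np.ndarray
    arc_positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        pts = _as_points(self.vertices, 2, "polyline")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= _MIN_VERTEX_SEP):
            bad = int(np.argmax(seg <= _MIN_VERTEX_SEP))
            raise DegenerateInputError(
                f"polyline vertices {bad} and {bad + 1} coincide (separation {seg[bad]:.3g} mm)"
            )
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "vertices", pts)
        object.__setattr__(self, "arc_positions", cum)

    @property
    def total_length(self) -> float:
        return float(self.arc_positions[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc position ``s`` (linear interpolation along segments)."""
        if s < -_ON_PLANE_TOL or s > self.total_length + _ON_PLANE_TOL:
            raise GeometryError(
                f"arc position {s} outside [0, {self.total_length}]"
            )
        s = min(max(s, 0.0), self.total_length)
        i = int(np.searchsorted(self.arc_positions, s, side="right") - 1)
        i = min(i, len(self.vertices) - 2)
        seg_len = self.arc_positions[i + 1] - self.arc_positions[i]
        t = (s - self.arc_positions[i]) / seg_len
        return (1.0 - t) * self.vertices[i] + t * self.vertices[i + 1]


def fit_plane(points) -> Plane:
    """Total-least-squares plane through a point cloud.

    Minimizes the sum of squared orthogonal distances (smallest principal
    direction of the centered cloud).  Raises :class:`DegenerateInputError`
    for fewer than 3 points or (near-)collinear input.
    """
    pts = _as_points(points, 3, "fit_plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(sing[0], 1.0)
    if sing[1] <= 1e-9 * scale:
        raise DegenerateInputError("fit_plane: points are collinear")
    normal = _orient_normal(vt[2])
    return Plane(point=centroid, normal=normal)


def _plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    n = plane.normal
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(seed - (seed @ n) * n)
    v = np.cross(n, u)
    return u, v


def fit_circle_3d(points, max_iter: int = 100, tol: float = 1e-9) -> Circle3D:
    """Fit a circle to 3-D points: plane projection, Kåsa algebraic fit, then
    geometric Gauss–Newton refinement.

    Convergence when the (center, radius) update falls below ``tol`` mm;
    non-convergence raises :class:`ConvergenceError` carrying the last iterate.
    """
    pts = _as_points(points, 3, "fit_circle_3d")
    plane = fit_plane(pts)  # raises on collinear input
    u, v = _plane_basis(plane)
    rel = pts - plane.point
    x = rel @ u
    y = rel @ v

    # Kåsa: (x - cx)^2 + (y - cy)^2 = r^2  ->  2 cx x + 2 cy y + k = x^2 + y^2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    (cx, cy, k), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(max(k + cx * cx + cy * cy, 1e-24)))

    params = np.array([cx, cy, r])
    converged = False
    for _ in range(max_iter):
        dx = x - params[0]
        dy = y - params[1]
        dist = np.hypot(dx, dy)
        dist = np.maximum(dist, 1e-12)
        residual = dist - params[2]
        J = np.column_stack([-dx / dist, -dy / dist, -np.ones_like(dist)])
        delta, *_ = np.linalg.lstsq(J, -residual, rcond=None)
        params = params + delta
        if np.linalg.norm(delta) < tol:
            converged = True
            break

    center3 = plane.point + params[0] * u + params[1] * v
    circle = Circle3D(center=center3, radius=float(params[2]), normal=plane.normal)
    if not converged:
        raise ConvergenceError(
            f"circle fit did not converge in {max_iter} iterations", last_iterate=circle
        )
    return circle


def polyline_arc_length(curve: Polyline3, s0: float, s1: float) -> float:
    """Length along the curve between arc positions ``s0 <= s1``."""
    total = curve.total_length
    if s0 < -_ON_PLANE_TOL or s1 > total + _ON_PLANE_TOL or s0 > s1 + _ON_PLANE_TOL:
        raise GeometryError(
            f"arc positions must satisfy 0 <= s0 <= s1 <= {total}; got ({s0}, {s1})"
        )
    return float(min(s1, total) - max(s0, 0.0))


def resample_polyline(curve: Polyline3, spacing: float) -> Polyline3:
    """Resample at equal steps of the chordal parameterization.

    Endpoints are preserved exactly; the final segment may be shorter than
    ``spacing``.  The resampled vertices lie on the original polygon.
    """
    if not spacing > 0:
        raise GeometryError(f"spacing must be positive, got {spacing}")
    total = curve.total_length
    if spacing >= total:
        raise GeometryError(f"spacing {spacing} mm >= curve length {total} mm")
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] <= _MIN_VERTEX_SEP:
        targets = targets[:-1]
    targets = np.append(targets, total)
    pts = np.column_stack(
        [np.interp(targets, curve.arc_positions, curve.vertices[:, k]) for k in range(3)]
    )
    pts[0] = curve.vertices[0]
    pts[-1] = curve.vertices[-1]
    return Polyline3(pts)


def plane_polyline_intersections(plane: Plane, curve: Polyline3) -> list[float]:
    """Arc positions where the curve crosses the plane, sorted ascending.

    One position per sign change of the signed distance, located by linear
    interpolation; a vertex lying on the plane (|distance| < 1e-9 mm) is
    reported once.  Returns an empty list when there is no crossing.
    """
    d = plane.signed_distance(curve.vertices)
    on = np.abs(d) < _ON_PLANE_TOL
    positions = list(curve.arc_positions[on])
    dprev, dnext = d[:-1], d[1:]
    crossing = (~on[:-1]) & (~on[1:]) & (np.sign(dprev) != np.sign(dnext))
    for i in np.nonzero(crossing)[0]:
        t = dprev[i] / (dprev[i] - dnext[i])
        s = curve.arc_positions[i] + t * (curve.arc_positions[i + 1] - curve.arc_positions[i])
        positions.append(float(s))
    return sorted(positions)


def _segment_geometry(curve: Polyline3):
    p = curve.vertices[:-1]
    q = curve.vertices[1:]
    v = q - p
    seg_len = curve.arc_positions[1:] - curve.arc_positions[:-1]
    return p, v, seg_len


def ray_polyline_intersection(
    origin, direction, curve: Polyline3, capture_radius: float
) -> float:
    """Arc position of the curve point nearest a ray, within a capture radius.

    A 3-D ray generically misses a polyline, so "intersection" is nearest
    approach: the closest curve point is accepted if its distance to the ray
    is at most ``capture_radius`` (closest ray parameter clamped to >= 0).
    Ties in distance resolve to the smaller arc position.
    """
    if not capture_radius > 0:
        raise GeometryError(f"capture_radius must be positive, got {capture_radius}")
    o = np.asarray(origin, dtype=float)
    u = _unit(direction, "ray direction")

    p, v, seg_len = _segment_geometry(curve)
    w = p - o
    b = v @ u
    c = np.einsum("ij,ij->i", v, v)
    d = w @ u
    e = np.einsum("ij,ij->i", v, w)

    denom = c - b * b
    safe_denom = np.where(denom > 1e-12, denom, 1.0)
    t = np.where(denom > 1e-12, (d * b - e) / safe_denom, 0.0)
    t = np.clip(t, 0.0, 1.0)
    s = d + t * b
    neg = s < 0.0
    if np.any(neg):
        t = np.where(neg, np.clip(-e / np.maximum(c, 1e-300), 0.0, 1.0), t)
        s = np.where(neg, 0.0, s)
    diff = s[:, None] * u[None, :] - t[:, None] * v - w
    dist = np.linalg.norm(diff, axis=1)

    dmin = float(dist.min())
    if dmin > capture_radius:
        raise NoIntersectionError(
            f"no curve point within capture radius {capture_radius} mm of the ray "
            f"(closest approach {dmin:.3g} mm)"
        )
    arc = curve.arc_positions[:-1] + t * seg_len
    candidates = dist <= dmin + _TIE_TOL
    return float(arc[candidates].min())


def project_point_to_polyline(point, curve: Polyline3) -> float:
    """Arc position of the closest point on the curve; ties -> smallest position."""
    s, _ = closest_point_on_polyline(point, curve)
    return s


def closest_point_on_polyline(point, curve: Polyline3) -> tuple[float, float]:
    """(arc position, distance) of the closest point on the curve to ``point``."""
    pt = np.asarray(point, dtype=float)
    p, v, seg_len = _segment_geometry(curve)
    c = np.einsum("ij,ij->i", v, v)
    t = np.clip(np.einsum("ij,ij->i", pt - p, v) / c, 0.0, 1.0)
    foot = p + t[:, None] * v
    dist = np.linalg.norm(foot - pt, axis=1)
    dmin = float(dist.min())
    arc = curve.arc_positions[:-1] + t * seg_len
    candidates = dist <= dmin + _TIE_TOL
    return float(arc[candidates].min()), dmin


def apply_rigid_transform(points, rotation: np.ndarray, translation) -> np.ndarray:
    """Apply ``R x + t`` to an (n, 3) array (convenience for tests and tools)."""
    pts = np.asarray(points, dtype=float)
    return pts @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)
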