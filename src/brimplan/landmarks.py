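"""Brim landmark construction and zone measurement.

The four named landmarks on the pelvic brim are:

* C — the sacroiliac joint end of the brim (arc position 0 by convention),
* A — where the transverse plane (perpendicular to the body axis) through the
  *superior* acetabular margin crosses the brim,
* B — where the line from the brim-circle center through the *inferior*
  acetabular margin meets the brim,
* D — the pubic symphysis end (arc position = total brim length).

They split the brim into zone a (C->A, safe), zone b (A->B, dangerous: it
overlies the acetabular socket) and zone c (B->D, safe).  All arc positions
are measured from the sacroiliac end along the brim curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LandmarkError, NoIntersectionError
from .geometry import (
    Circle3D,
    Plane,
    Polyline3,
    closest_point_on_polyline,
    fit_circle_3d,
    plane_polyline_intersections,
    ray_polyline_intersection,
    resample_polyline,
)
from .model import HemiPelvisModel

#: resampling step (mm) applied to the brim before intersection queries;
#: chordal error at this step is orders of magnitude below the 0.5 mm
#: recovery contract
DEFAULT_SPACING = 0.2
#: nearest-approach acceptance radius (mm) for the point-B ray construction
DEFAULT_CAPTURE_RADIUS = 2.0

_PROJ_TIE_TOL = 1e-9  # mm, ties in body-axis projection


@dataclass(frozen=True)
class BrimLandmarks:
    """Arc positions (mm from the sacroiliac end) of the brim landmarks."""

    s_A: float
    s_B: float
    s_D: float
    brim_circle: Circle3D
    s_C: float = 0.0

    def __post_init__(self):
        if not self.s_C < self.s_A < self.s_B < self.s_D:
            raise LandmarkError(
                f"landmark ordering violated: C={self.s_C}, A={self.s_A}, "
                f"B={self.s_B}, D={self.s_D}"
            )


@dataclass(frozen=True)
class ZoneLengths:
    """Zone lengths a, b, c and the total brim length, all in mm."""

    a: float
    b: float
    c: float
    total: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise LandmarkError(f"zone lengths must be positive: {self}")
        if abs(self.a + self.b + self.c - self.total) > 1e-6:
            raise LandmarkError(f"zones do not sum to the total length: {self}")


def _extremal_rim_point(model: HemiPelvisModel, sign: float) -> np.ndarray:
    rim = model.acetabulum.rim_points
    proj = sign * (rim @ model.body_axis)
    best = float(proj.max())
    tied = np.nonzero(proj >= best - _PROJ_TIE_TOL)[0]
    if len(tied) == 1:
        return rim[tied[0]]
    # tie rule: the candidate closest to the brim
    dists = [closest_point_on_polyline(rim[i], model.brim)[1] for i in tied]
    return rim[tied[int(np.argmin(dists))]]


def superior_acetabular_margin(model: HemiPelvisModel) -> np.ndarray:
    """Rim point with maximal projection on the body axis (cranial-most)."""
    return _extremal_rim_point(model, +1.0)


def inferior_acetabular_margin(model: HemiPelvisModel) -> np.ndarray:
    """Rim point with minimal projection on the body axis (caudal-most)."""
    return _extremal_rim_point(model, -1.0)


def _measurement_curve(model: HemiPelvisModel, spacing: float) -> Polyline3:
    return resample_polyline(model.brim, spacing)


def locate_point_A(
    model: HemiPelvisModel,
    spacing: float = DEFAULT_SPACING,
    curve: Polyline3 | None = None,
) -> float:
    """Arc position of point A.

    Intersects the transverse plane through the superior acetabular margin
    with the (resampled) brim.  On an anatomic brim the crossing is unique;
    should several exist, the one whose brim point lies closest to the
    acetabular center is taken.
    """
    if curve is None:
        curve = _measurement_curve(model, spacing)
    margin = superior_acetabular_margin(model)
    plane = Plane(point=margin, normal=model.body_axis)
    hits = plane_polyline_intersections(plane, curve)
    if not hits:
        raise LandmarkError(
            "point A: the transverse plane through the superior acetabular margin "
            "does not cross the brim"
        )
    if len(hits) == 1:
        return hits[0]
    center = model.acetabulum.reference_center
    dists = [np.linalg.norm(curve.point_at(s) - center) for s in hits]
    return hits[int(np.argmin(dists))]


def locate_point_B(
    model: HemiPelvisModel,
    brim_circle: Circle3D,
    spacing: float = DEFAULT_SPACING,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    curve: Polyline3 | None = None,
) -> float:
    """Arc position of point B.

    Casts the ray from the fitted brim-circle center through the inferior
    acetabular margin and takes its nearest approach to the (resampled)
    brim.  The capture radius absorbs the out-of-plane component of the ray
    relative to the discretized curve.
    """
    if curve is None:
        curve = _measurement_curve(model, spacing)
    margin = inferior_acetabular_margin(model)
    direction = margin - brim_circle.center
    if np.linalg.norm(direction) < 1e-9:
        raise LandmarkError("point B: inferior margin coincides with the brim-circle center")
    try:
        return ray_polyline_intersection(brim_circle.center, direction, curve, capture_radius)
    except NoIntersectionError as exc:
        raise LandmarkError(f"point B: {exc}") from exc


def compute_landmarks(
    model: HemiPelvisModel,
    spacing: float = DEFAULT_SPACING,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
) -> BrimLandmarks:
    """Fit the brim circle and locate all four landmarks on one model."""
    curve = _measurement_curve(model, spacing)
    circle = fit_circle_3d(model.brim.vertices)
    s_a = locate_point_A(model, curve=curve)
    s_b = locate_point_B(model, circle, capture_radius=capture_radius, curve=curve)
    if not s_a < s_b:
        raise LandmarkError(f"point A (s={s_a:.2f}) must precede point B (s={s_b:.2f})")
    return BrimLandmarks(s_A=s_a, s_B=s_b, s_D=curve.total_length, brim_circle=circle)


def zone_lengths(model: HemiPelvisModel, landmarks: BrimLandmarks) -> ZoneLengths:
    """Zone lengths from the landmark arc positions: a = C->A, b = A->B, c = B->D."""
    return ZoneLengths(
        a=landmarks.s_A - landmarks.s_C,
        b=landmarks.s_B - landmarks.s_A,
        c=landmarks.s_D - landmarks.s_B,
        total=landmarks.s_D - landmarks.s_C,
    )


def measure(model: HemiPelvisModel, spacing: float = DEFAULT_SPACING) -> ZoneLengths:
    """Convenience: landmarks + zone lengths in one call."""
    return zone_lengths(model, compute_landmarks(model, spacing=spacing))
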