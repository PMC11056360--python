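"""In-memory hemi-pelvis model: brim polyline + acetabular rim + body axis.

The brim runs, ordered, from the sacroiliac joint end (point C, arc position
0) to the pubic symphysis end (point D).  The acetabular rim is an ordered
point set on the bony socket margin, optionally carrying the fitted socket
sphere.  The body axis is the cranial (head-ward) unit direction of the frame
the model lives in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import Polyline3, _as_points, _unit

#: Sanity gate (mm) on total brim length: adult hemi-pelvis brims measure
#: roughly 120-160 mm; anything outside (80, 220) is not anatomy.
BRIM_LENGTH_RANGE = (80.0, 220.0)

MIN_RIM_POINTS = 8
SPHERE_BAND_TOL = 1.0  # mm; rim points must lie this close to the socket sphere


@dataclass(frozen=True)
class AcetabulumModel:
    """Acetabular rim point set, optionally with the socket sphere."""

    rim_points: np.ndarray
    sphere_center: np.ndarray | None = None
    sphere_radius: float | None = None

    def __post_init__(self):
        pts = _as_points(self.rim_points, MIN_RIM_POINTS, "acetabular rim")
        object.__setattr__(self, "rim_points", pts)
        has_center = self.sphere_center is not None
        has_radius = self.sphere_radius is not None
        if has_center != has_radius:
            raise GeometryError("sphere_center and sphere_radius must be given together")
        if has_center:
            center = np.asarray(self.sphere_center, dtype=float)
            radius = float(self.sphere_radius)
            if not radius > 0:
                raise GeometryError(f"sphere radius must be positive, got {radius}")
            dev = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
            worst = float(dev.max())
            if worst > SPHERE_BAND_TOL:
                raise GeometryError(
                    f"rim point deviates {worst:.3g} mm from the socket sphere "
                    f"(tolerance {SPHERE_BAND_TOL} mm)"
                )
            object.__setattr__(self, "sphere_center", center)
            object.__setattr__(self, "sphere_radius", radius)

    @property
    def reference_center(self) -> np.ndarray:
        """Socket sphere center when present, else the rim centroid."""
        if self.sphere_center is not None:
            return self.sphere_center
        return self.rim_points.mean(axis=0)


@dataclass(frozen=True)
class HemiPelvisModel:
    """A hemi-pelvis reduced to the structures the measurement needs."""

    brim: Polyline3
    acetabulum: AcetabulumModel
    body_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    side: str = "left"
    sex: str = "male"

    def __post_init__(self):
        object.__setattr__(self, "body_axis", _unit(self.body_axis, "body axis"))
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sex not in ("male", "female"):
            raise GeometryError(f"sex must be 'male' or 'female', got {self.sex!r}")
        lo, hi = BRIM_LENGTH_RANGE
        total = self.brim.total_length
        if not lo < total < hi:
            raise GeometryError(
                f"brim length {total:.1f} mm outside the anatomic range ({lo}, {hi}) mm"
            )

    def transformed(self, rotation, translation) -> "HemiPelvisModel":
        """The same model under a rigid motion (rotation applied to the axis too)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        acet = self.acetabulum
        return HemiPelvisModel(
            brim=Polyline3(self.brim.vertices @ R.T + t),
            acetabulum=AcetabulumModel(
                rim_points=acet.rim_points @ R.T + t,
                sphere_center=None if acet.sphere_center is None else R @ acet.sphere_center + t,
                sphere_radius=acet.sphere_radius,
            ),
            body_axis=R @ self.body_axis,
            side=self.side,
            sex=self.sex,
        )
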