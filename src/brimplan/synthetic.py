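"""Parametric hemi-pelvis generator with known ground truth.

The study data behind the zone-length tables are CT reconstructions that are
not publicly deposited, so this module builds hemi-pelves *backwards*: you
state the zone lengths a (sacroiliac joint -> A), b (A -> B, over the socket)
and c (B -> symphysis), and the generator constructs a brim arc and an
acetabular rim for which those are exactly the ground-truth answers.  The
landmark pipeline can then be validated end-to-end against construction.

Construction outline (left side; the right side is its mirror image):

* The brim is an arc of a circle of radius ``brim_radius`` lying in a plane
  inclined ``brim_plane_tilt`` degrees from the transverse plane, sampled as
  an equal-chord polyline per zone so that the cumulative chord positions of
  the landmark vertices are *exactly* a, a+b and a+b+c.
* The inferior acetabular rim point sits on the ray from the brim-circle
  center through brim point B, at ``lateral_offset_factor`` times the radius:
  the point-B construction (center -> inferior margin ray) recovers B exactly.
* The superior rim point is placed lateral to the brim with its cranial
  coordinate equal to that of brim point A: the point-A construction (the
  transverse plane through the superior margin) recovers A exactly.
* The rim circle takes the superior/inferior points as a diameter pair, with
  the in-plane basis chosen so they are the unique cranial/caudal extremes of
  the rim point set.  The socket sphere is centered on the rim-circle axis.
* Optional noise is a smooth correlated perturbation field (not white noise):
  Gaussian control points roughly every 15 mm, cubic-spline interpolated,
  per-point norm clipped at 3 sd.  This emulates segmentation/reconstruction
  error while leaving chordal arc length calibrated.

Cohorts follow the four study groups (male/female x left/right) with zone
lengths drawn from per-group normal distributions truncated at +-3 SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConstructionError
from .geometry import Polyline3
from .model import AcetabulumModel, HemiPelvisModel
from .reference import REFERENCE_GROUP_SIZES, REFERENCE_ZONES

#: chord length (mm) used when sampling the brim arc into a polyline
BRIM_SAMPLING_STEP = 0.5
#: correlation length (mm) of the smooth noise field
NOISE_CORRELATION_LENGTH = 15.0
#: horizontal offset (mm) of the superior rim point lateral to brim point A
SUPERIOR_MARGIN_OFFSET = 10.0

_LATERAL = np.array([0.0, -1.0, 0.0])  # horizontal "away from the inlet" direction
_GROUP_SIDE_SEX = {
    "ML": ("male", "left"),
    "MR": ("male", "right"),
    "FL": ("female", "left"),
    "FR": ("female", "right"),
}


@dataclass(frozen=True)
class PelvisSpec:
    """Targets and shape parameters for one synthetic hemi-pelvis.

    ``target_a/b/c`` are the ground-truth zone lengths in mm.  The default
    brim radius of 44 mm makes a ~139 mm brim span roughly a half circle,
    which is the anatomically plausible regime; the 60 degree tilt mimics the
    pelvic-inlet inclination seen in the inlet-obturator orientation.
    """

    target_a: float
    target_b: float
    target_c: float
    brim_radius: float = 44.0
    brim_plane_tilt: float = 60.0
    acetab_radius: float = 24.0
    lateral_offset_factor: float = 1.15
    rim_point_count: int = 72
    noise_sd: float = 0.0
    side: str = "left"
    sex: str = "male"

    def __post_init__(self):
        for name in ("target_a", "target_b", "target_c"):
            if not getattr(self, name) > 0:
                raise ConstructionError(f"{name} must be positive")
        if not self.brim_radius > 0:
            raise ConstructionError("brim_radius must be positive")
        if not 0 < self.brim_plane_tilt < 90:
            raise ConstructionError("brim_plane_tilt must lie in (0, 90) degrees")
        if self.rim_point_count < 8 or self.rim_point_count % 2:
            raise ConstructionError("rim_point_count must be an even integer >= 8")
        if self.noise_sd < 0:
            raise ConstructionError("noise_sd must be >= 0")
        if self.side not in ("left", "right") or self.sex not in ("male", "female"):
            raise ConstructionError(f"bad side/sex: {self.side!r}/{self.sex!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows exactly (pre-noise)."""

    a: float
    b: float
    c: float
    s_A: float
    s_B: float
    total: float
    superior_rim_point: np.ndarray
    inferior_rim_point: np.ndarray


@dataclass(frozen=True)
class GroupParams:
    """Per-group cohort parameters: sample size and zone mean/SD in mm."""

    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_c: float
    sd_c: float

    def __post_init__(self):
        if self.n < 1:
            raise ConstructionError("group size must be >= 1")
        if min(self.sd_a, self.sd_b, self.sd_c) < 0:
            raise ConstructionError("SDs must be >= 0")


def _default_groups() -> dict[str, GroupParams]:
    out = {}
    for g, zones in REFERENCE_ZONES.items():
        out[g] = GroupParams(
            n=REFERENCE_GROUP_SIZES[g],
            mean_a=float(zones["a"][0]), sd_a=float(zones["a"][1]),
            mean_b=float(zones["b"][0]), sd_b=float(zones["b"][1]),
            mean_c=float(zones["c"][0]), sd_c=float(zones["c"][1]),
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Cohort description: group sizes and zone distributions (defaults = the
    four study groups), plus the master seed."""

    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        for g in self.groups:
            if g not in _GROUP_SIDE_SEX:
                raise ConstructionError(f"unknown group label {g!r}")


def _zone_chords(length: float, radius: float) -> tuple[int, float, float]:
    """Split one zone into equal chords on the radius-R circle.

    Returns (segment count, chord length, angular step).  Chord positions are
    exact by construction: n chords of length L/n accumulate to exactly L.
    """
    n = max(1, math.ceil(length / BRIM_SAMPLING_STEP))
    chord = length / n
    if chord >= 2 * radius:
        raise ConstructionError(
            f"zone of length {length} mm cannot be sampled on a circle of radius {radius} mm"
        )
    return n, chord, 2.0 * math.asin(chord / (2.0 * radius))


def _smooth_noise(rng: np.random.Generator, positions: np.ndarray, sd: float,
                  periodic: bool = False) -> np.ndarray:
    """Smooth random perturbation field sampled at ``positions`` (mm).

    Gaussian control points every ~NOISE_CORRELATION_LENGTH mm, cubic-spline
    interpolated per coordinate; per-point vector norm clipped at 3 sd so a
    perturbed rim always stays inside the model's sphere-consistency band.
    """
    if sd == 0.0:
        return np.zeros((len(positions), 3))
    span = float(positions[-1] - positions[0])
    n_ctrl = max(2, int(round(span / NOISE_CORRELATION_LENGTH)) + 1)
    knots = np.linspace(positions[0], positions[-1], n_ctrl)
    ctrl = rng.normal(0.0, sd, size=(n_ctrl, 3))
    if periodic:
        ctrl[-1] = ctrl[0]
        spline = CubicSpline(knots, ctrl, bc_type="periodic")
    else:
        spline = CubicSpline(knots, ctrl, bc_type="natural")
    noise = spline(positions)
    norms = np.linalg.norm(noise, axis=1)
    cap = 3.0 * sd
    over = norms > cap
    if np.any(over):
        noise[over] *= (cap / norms[over])[:, None]
    return noise


def build_pelvis(spec: PelvisSpec, seed: int = 0) -> tuple[HemiPelvisModel, GroundTruth]:
    """Construct one hemi-pelvis model and its exact ground truth.

    Deterministic given (spec, seed); the seed only feeds the noise field.
    Raises :class:`ConstructionError` naming the violated step when the
    requested geometry is infeasible.
    """
    R = spec.brim_radius
    tilt = math.radians(spec.brim_plane_tilt)
    a, b, c = spec.target_a, spec.target_b, spec.target_c

    # --- step 1: brim arc, equal-chord sampled per zone, ordered C -> D ----
    steps = [_zone_chords(z, R) for z in (a, b, c)]
    total_angle = sum(n * dth for n, _, dth in steps)
    if total_angle >= 2.0 * math.pi:
        raise ConstructionError(
            "brim arc: requested zone lengths wrap the full circle "
            f"(arc angle {math.degrees(total_angle):.1f} deg)"
        )
    e1 = np.array([1.0, 0.0, 0.0]) if spec.side == "left" else np.array([-1.0, 0.0, 0.0])
    e2 = np.array([0.0, math.cos(tilt), math.sin(tilt)])

    thetas = [total_angle / 2.0]
    for n, _, dth in steps:
        for _ in range(n):
            thetas.append(thetas[-1] - dth)
    thetas = np.asarray(thetas)
    brim = R * (np.cos(thetas)[:, None] * e1 + np.sin(thetas)[:, None] * e2)

    n_a = steps[0][0]
    n_b = steps[1][0]
    point_A = brim[n_a]
    point_B = brim[n_a + n_b]

    # --- steps 3-4: acetabular margin points -------------------------------
    t = spec.lateral_offset_factor
    p_inf = t * point_B  # brim-circle center is the origin here
    p_sup = point_A + SUPERIOR_MARGIN_OFFSET * _LATERAL
    if abs(p_sup[2] - p_inf[2]) < 1e-9:
        raise ConstructionError(
            "acetabular margins: superior and inferior rim points are at the same "
            "cranial height; rim extremes would be ambiguous"
        )

    # --- step 5: rim circle through the margin diameter pair ---------------
    diameter = p_sup - p_inf
    r_rim = float(np.linalg.norm(diameter)) / 2.0
    # the nominal socket radius is a floor: extreme zone targets can make the
    # margin chord wider than a typical socket, so the sphere grows to fit
    socket_radius = max(spec.acetab_radius, r_rim + 1.0)
    u = diameter / (2.0 * r_rim)
    horiz = np.array([-u[1], u[0], 0.0])
    h_norm = np.linalg.norm(horiz)
    if h_norm < 1e-12:
        raise ConstructionError("rim circle: margin diameter is vertical; no horizontal basis")
    v = horiz / h_norm
    mid = (p_sup + p_inf) / 2.0
    psi = 2.0 * math.pi * np.arange(spec.rim_point_count) / spec.rim_point_count
    rim = mid + r_rim * (np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v)
    rim[0] = p_sup
    rim[spec.rim_point_count // 2] = p_inf

    # --- step 6: socket sphere on the rim-circle axis, lateral side --------
    axis = np.cross(u, v)
    if axis @ _LATERAL < 0:
        axis = -axis
    offset = math.sqrt(socket_radius**2 - r_rim**2)
    sphere_center = mid + offset * axis

    truth = GroundTruth(
        a=a, b=b, c=c, s_A=a, s_B=a + b, total=a + b + c,
        superior_rim_point=p_sup.copy(), inferior_rim_point=p_inf.copy(),
    )

    # --- step 7: smooth correlated noise -----------------------------------
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        brim_pos = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(brim, axis=0), axis=1))])
        brim = brim + _smooth_noise(rng, brim_pos, spec.noise_sd)
        rim_pos = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(rim, axis=0), axis=1))])
        rim = rim + _smooth_noise(rng, rim_pos, spec.noise_sd, periodic=False)

    model = HemiPelvisModel(
        brim=Polyline3(brim),
        acetabulum=AcetabulumModel(
            rim_points=rim, sphere_center=sphere_center, sphere_radius=socket_radius
        ),
        body_axis=np.array([0.0, 0.0, 1.0]),
        side=spec.side,
        sex=spec.sex,
    )
    return model, truth


def sample_zone_lengths(params: GroupParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n (a, b, c) triples from the group's truncated normals (+-3 SD)."""
    out = np.empty((n, 3))
    for j, (mean, sd) in enumerate(
        [(params.mean_a, params.sd_a), (params.mean_b, params.sd_b), (params.mean_c, params.sd_c)]
    ):
        draw = rng.normal(mean, sd, size=n)
        if sd > 0:
            bad = np.abs(draw - mean) > 3.0 * sd
            while np.any(bad):
                draw[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = np.abs(draw - mean) > 3.0 * sd
        out[:, j] = draw
    return out


def generate_cohort(
    cohort: CohortSpec,
) -> list[tuple[HemiPelvisModel, GroundTruth, str]]:
    """Generate one model per subject across all groups.

    Zone triples are drawn independently per subject from the group's
    truncated normal distributions; each model is then built by
    :func:`build_pelvis` with a per-subject seed spawned from the cohort seed.
    """
    rng = np.random.default_rng(cohort.seed)
    out = []
    for group in sorted(cohort.groups):  # deterministic order: FL, FR, ML, MR
        params = cohort.groups[group]
        sex, side = _GROUP_SIDE_SEX[group]
        triples = sample_zone_lengths(params, params.n, rng)
        seeds = rng.integers(0, 2**31 - 1, size=params.n)
        for (za, zb, zc), s in zip(triples, seeds):
            spec = PelvisSpec(
                target_a=float(za), target_b=float(zb), target_c=float(zc),
                noise_sd=cohort.noise_sd, side=side, sex=sex,
            )
            model, truth = build_pelvis(spec, seed=int(s))
            out.append((model, truth, group))
    return out


def reference_mean_spec(group: str = "ML", **overrides) -> PelvisSpec:
    """A PelvisSpec whose targets are one study group's mean zone lengths."""
    zones = REFERENCE_ZONES[group]
    sex, side = _GROUP_SIDE_SEX[group]
    spec = PelvisSpec(
        target_a=float(zones["a"][0]),
        target_b=float(zones["b"][0]),
        target_c=float(zones["c"][0]),
        side=side,
        sex=sex,
    )
    return replace(spec, **overrides) if overrides else spec
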