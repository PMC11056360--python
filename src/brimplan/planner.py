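"""Screw-placement planning on the measured brim.

Zones a and c (either side of the acetabular socket) are safe for drilling
through the Stoppa window; zone b overlies the socket and is dangerous.  The
plan arithmetic is deliberately simple:

* safe screw count per safe zone: the largest n with n*d <= zone length,
* vacant holes over zone b: the smallest n whose span e_n covers b,
* clinically quotable safe ranges measured from the pubic symphysis
  ([0, c] and [c+b, total]; with mean anatomy this is the 0-6 cm / 10-14 cm
  rule, the band 6-10 cm being off limits),
* for acetabular fractures, a fracture line inside zone b anchors a
  "reference hole" that is never drilled; which neighbours are also skipped
  depends on the third of zone b the fracture falls in.

Direction convention (documented here because it is easy to get backwards):
hole offsets are counted with *distal = toward the pubic symphysis* positive
and *proximal = toward the sacroiliac joint* negative.  A superior-third
fracture leaves the dangerous remainder on the symphysis side, hence skips
the two distally adjacent holes, and symmetrically for the inferior third.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PlanError
from .landmarks import BrimLandmarks, ZoneLengths
from .plates import PlateSpec, SpanTable, span_length

_TOL = 1e-9

THIRDS = ("superior", "middle", "inferior")

#: hole offsets (relative to the reference hole; + = distal, toward the
#: symphysis) that must stay vacant for a fracture in each third of zone b;
#: the reference hole itself (offset 0) is always vacant
SKIP_OFFSETS = {
    "superior": frozenset({0, +1, +2}),
    "middle": frozenset({-1, 0, +1}),
    "inferior": frozenset({-2, -1, 0}),
}


@dataclass(frozen=True)
class FractureLineInfo:
    """A brim fracture line, located by its arc position from the symphysis."""

    position_from_symphysis: float
    third: str | None = None  # filled in by the planner

    def __post_init__(self):
        if not self.position_from_symphysis >= 0:
            raise PlanError("fracture position must be >= 0 mm from the symphysis")
        if self.third is not None and self.third not in THIRDS:
            raise PlanError(f"unknown zone-b third {self.third!r}")


@dataclass(frozen=True)
class HoleRecord:
    """One plate hole in the plan (positions from the symphysis, mm)."""

    index: int
    position_from_symphysis: float
    zone: str  # 'a' | 'b' | 'c'
    action: str  # 'drill' | 'skip'
    reason: str


@dataclass(frozen=True)
class SafeRanges:
    """Symphysis-referenced drilling ranges (mm)."""

    safe_intervals: tuple[tuple[float, float], ...]
    dangerous_interval: tuple[float, float] | None


@dataclass(frozen=True)
class ScrewPlan:
    """A complete per-hole drill/skip schedule plus its summary counts."""

    n_screws_zone_a: int
    n_screws_zone_c: int
    n_vacant_zone_b: int
    safe_intervals_from_symphysis: tuple[tuple[float, float], ...]
    dangerous_interval: tuple[float, float] | None
    hole_schedule: tuple[HoleRecord, ...]
    fracture: FractureLineInfo | None = None
    warnings: tuple[str, ...] = field(default=())

    @property
    def summary(self) -> str:
        """The 'screws in a / vacant in b / screws in c' summary, e.g. '3/3/4'."""
        return f"{self.n_screws_zone_a}/{self.n_vacant_zone_b}/{self.n_screws_zone_c}"

    def to_dict(self) -> dict:
        return {
            "n_screws_zone_a": self.n_screws_zone_a,
            "n_screws_zone_c": self.n_screws_zone_c,
            "n_vacant_zone_b": self.n_vacant_zone_b,
            "summary": self.summary,
            "safe_intervals_from_symphysis_mm": [list(i) for i in self.safe_intervals_from_symphysis],
            "dangerous_interval_mm": None if self.dangerous_interval is None else list(self.dangerous_interval),
            "fracture_position_from_symphysis_mm": None if self.fracture is None else self.fracture.position_from_symphysis,
            "fracture_third": None if self.fracture is None else self.fracture.third,
            "warnings": list(self.warnings),
            "hole_schedule": [
                {
                    "index": h.index,
                    "position_from_symphysis_mm": h.position_from_symphysis,
                    "zone": h.zone,
                    "action": h.action,
                    "reason": h.reason,
                }
                for h in self.hole_schedule
            ],
        }


def safe_screw_count(zone_length: float, d: float) -> int:
    """Largest n with n*d <= zone length (equality counts as safe)."""
    if not d > 0:
        raise PlanError(f"hole spacing d must be positive, got {d}")
    if zone_length < 0:
        raise PlanError(f"zone length must be >= 0, got {zone_length}")
    return int(math.floor(zone_length / d + _TOL))


def vacant_hole_count(b_length: float, plate: PlateSpec, table: SpanTable | None = None) -> int:
    """Smallest n whose vacant span e_n covers zone b (e_n >= b)."""
    if not b_length > 0:
        raise PlanError(f"zone b length must be positive, got {b_length}")
    n = 1
    while span_length(plate, n, table) < b_length - _TOL:
        n += 1
        if n > 1000:  # unreachable: the parametric span grows linearly
            raise PlanError("vacant span does not cover zone b")
    return n


def _zone_abc(zones) -> tuple[float, float, float]:
    if isinstance(zones, ZoneLengths):
        return zones.a, zones.b, zones.c
    a, b, c = zones
    return float(a), float(b), float(c)


def symphysis_safe_ranges(zones) -> SafeRanges:
    """Safe and dangerous drilling ranges measured from the pubic symphysis.

    Safe: [0, c] and [c + b, total]; dangerous: the open band (c, c + b).
    Accepts a :class:`ZoneLengths` or a plain (a, b, c) triple (the latter
    admits the degenerate b = 0 case, where the safe ranges merge).
    """
    a, b, c = _zone_abc(zones)
    total = a + b + c
    if b <= _TOL:
        return SafeRanges(safe_intervals=((0.0, total),), dangerous_interval=None)
    return SafeRanges(
        safe_intervals=((0.0, c), (c + b, total)),
        dangerous_interval=(c, c + b),
    )


def classify_fracture_third(s_fracture: float, landmarks: BrimLandmarks) -> str:
    """Which equal third of zone b a fracture falls in.

    ``s_fracture`` is an arc position from the *sacroiliac* end and must lie
    inside [s_A, s_B].  Boundaries belong to the more superior (sacroiliac-
    side) third.
    """
    s_a, s_b = landmarks.s_A, landmarks.s_B
    if s_fracture < s_a - _TOL or s_fracture > s_b + _TOL:
        raise PlanError(
            f"fracture position {s_fracture:.2f} mm outside zone b "
            f"[{s_a:.2f}, {s_b:.2f}]"
        )
    b = s_b - s_a
    rel = min(max(s_fracture - s_a, 0.0), b)
    if rel <= b / 3.0 + _TOL:
        return "superior"
    if rel <= 2.0 * b / 3.0 + _TOL:
        return "middle"
    return "inferior"


def skip_set(third: str) -> frozenset[int]:
    """Vacant-hole offsets (reference hole = 0; + = toward the symphysis)."""
    try:
        return SKIP_OFFSETS[third]
    except KeyError:
        raise PlanError(f"unknown zone-b third {third!r}") from None


def _hole_zone(pos: float, b: float, c: float) -> str:
    # hole centers on a zone boundary count as safe
    if pos <= c + _TOL:
        return "c"
    if pos >= c + b - _TOL:
        return "a"
    return "b"


def plan_plate(
    landmarks: BrimLandmarks,
    zones: ZoneLengths,
    plate: PlateSpec,
    first_hole_position_from_symphysis: float,
    n_holes: int,
    fracture: FractureLineInfo | None = None,
    table: SpanTable | None = None,
) -> ScrewPlan:
    """Lay a plate along the brim and assign drill/skip to every hole.

    Hole centers sit at ``first + k*d`` from the symphysis (index 0 nearest
    the symphysis).  Without fracture information every zone-b hole is
    skipped.  With a fracture line, the hole nearest the fracture becomes
    the (undrilled) reference hole and the third-specific offsets are
    skipped *instead of* the blanket zone-b rule — zone-b holes drilled
    under that rule are flagged in the schedule.
    """
    if not 2 <= n_holes <= 16:
        raise PlanError(f"n_holes must be in [2, 16], got {n_holes}")
    first = float(first_hole_position_from_symphysis)
    if first < 0:
        raise PlanError(f"first hole position must be >= 0, got {first}")
    a, b, c = zones.a, zones.b, zones.c
    total = zones.total
    positions = first + plate.d * np.arange(n_holes)
    if positions[-1] > total + _TOL:
        raise PlanError(
            f"plate overhangs the brim: last hole at {positions[-1]:.2f} mm, "
            f"brim length {total:.2f} mm"
        )
    hole_zones = [_hole_zone(p, b, c) for p in positions]

    skip_idx: dict[int, str] = {}
    frac = None
    if fracture is None:
        for k, z in enumerate(hole_zones):
            if z == "b":
                skip_idx[k] = "dangerous zone b"
    else:
        f_pos = fracture.position_from_symphysis
        if f_pos > total + _TOL:
            raise PlanError(f"fracture position {f_pos:.2f} mm beyond the brim end")
        ref = int(np.argmin(np.abs(positions - f_pos)))
        if hole_zones[ref] != "b":
            raise PlanError(
                f"reference hole (index {ref}, {positions[ref]:.2f} mm) lies in "
                f"zone {hole_zones[ref]}, not in zone b"
            )
        third = classify_fracture_third(total - f_pos, landmarks)
        frac = FractureLineInfo(position_from_symphysis=f_pos, third=third)
        for off in skip_set(third):
            k = ref - off  # +offset is distal: toward the symphysis, lower index
            if 0 <= k < n_holes:
                skip_idx[k] = (
                    "reference hole (on fracture line)" if off == 0
                    else f"fracture rule: {third} third, offset {off:+d}"
                )

    schedule = []
    for k, (pos, z) in enumerate(zip(positions, hole_zones)):
        if k in skip_idx:
            schedule.append(HoleRecord(k, float(pos), z, "skip", skip_idx[k]))
        else:
            reason = f"safe zone {z}" if z != "b" else "zone b drilled under fracture rule"
            schedule.append(HoleRecord(k, float(pos), z, "drill", reason))

    drilled = [h for h in schedule if h.action == "drill"]
    n_a = sum(1 for h in drilled if h.zone == "a")
    n_c = sum(1 for h in drilled if h.zone == "c")
    n_vac_b = sum(1 for h in schedule if h.action == "skip" and h.zone == "b")

    warnings = []
    for zone_name, zone_len, count in (("a", a, n_a), ("c", c, n_c)):
        limit = safe_screw_count(zone_len, plate.d)
        if count > limit:
            warnings.append(
                f"{count} screws drilled in zone {zone_name} exceed the n*d <= "
                f"{zone_name} bound ({limit})"
            )
    if fracture is None:
        lo, hi = c, c + b
        for h in drilled:  # guaranteed by construction; cheap invariant check
            if lo + _TOL < h.position_from_symphysis < hi - _TOL:
                raise PlanError(f"internal error: drilled hole {h.index} inside zone b")

    ranges = symphysis_safe_ranges(zones)
    return ScrewPlan(
        n_screws_zone_a=n_a,
        n_screws_zone_c=n_c,
        n_vacant_zone_b=n_vac_b,
        safe_intervals_from_symphysis=ranges.safe_intervals,
        dangerous_interval=ranges.dangerous_interval,
        hole_schedule=tuple(schedule),
        fracture=frac,
        warnings=tuple(warnings),
    )
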