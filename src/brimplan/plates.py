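"""Reconstruction-plate hole geometry.

A pelvic reconstruction plate is modelled by two quantities measured on real
plates: the center-to-center spacing of adjacent holes, d, and the "span"
lengths e_1..e_4 across one to four consecutive vacant holes.  Four
manufacturers' plates ship as a built-in catalogue (packaged CSV) together
with a column-mean row; the means use round-half-up to two decimals.

The catalogue does not state how e_n relates to d, but the data are well
explained by the affine model ``e_n = (n + 1) d - h`` with h a constant close
to a hole diameter (residuals below 0.7 mm on all rows).  That model extends
the spans beyond n = 4; tabulated values always take precedence where they
exist.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import Decimal
from typing import NamedTuple

import pandas as pd

from .errors import BrimplanError
from .reference import round_half_up

#: fallback hole diameter (mm) for the parametric span model
DEFAULT_HOLE_DIAMETER = 5.1

MEAN_LABEL = "Mean"


class PlateError(BrimplanError, ValueError):
    """Invalid plate description or span request."""


@dataclass(frozen=True)
class PlateSpec:
    """One plate: label, adjacent-hole spacing d (mm) and hole count."""

    manufacturer: str
    d: float
    hole_count: int = 10
    hole_diameter: float | None = None

    def __post_init__(self):
        if not self.d > 0:
            raise PlateError(f"hole spacing d must be positive, got {self.d}")
        if self.hole_count < 2:
            raise PlateError(f"hole_count must be >= 2, got {self.hole_count}")
        if self.hole_diameter is not None and not 0 < self.hole_diameter < self.d:
            raise PlateError(
                f"hole_diameter must lie in (0, d={self.d}), got {self.hole_diameter}"
            )


@dataclass(frozen=True)
class SpanTable:
    """Catalogue of plate rows (d, e1..e4 in mm) plus a derived mean row."""

    rows: pd.DataFrame  # index: manufacturer; columns d, e1..e4 (floats)

    def __post_init__(self):
        df = self.rows
        required = ["d", "e1", "e2", "e3", "e4"]
        if list(df.columns) != required:
            raise PlateError(f"span table needs columns {required}, got {list(df.columns)}")
        for name, row in df.iterrows():
            e = [row[f"e{n}"] for n in range(1, 5)]
            if not all(e[i] < e[i + 1] for i in range(3)):
                raise PlateError(f"row {name!r}: spans e1..e4 must be strictly increasing")
            if not all(e[n - 1] < (n + 1) * row["d"] for n in range(1, 5)):
                raise PlateError(f"row {name!r}: e_n must stay below (n+1)*d")

    @property
    def manufacturers(self) -> list[str]:
        return [m for m in self.rows.index if m != MEAN_LABEL]

    def row(self, manufacturer: str) -> pd.Series:
        try:
            return self.rows.loc[manufacturer]
        except KeyError:
            raise PlateError(f"unknown manufacturer {manufacturer!r}") from None

    def plate(self, manufacturer: str, hole_count: int = 10) -> PlateSpec:
        row = self.row(manufacturer)
        return PlateSpec(manufacturer=manufacturer, d=float(row["d"]), hole_count=hole_count)


class HoleDiameterFit(NamedTuple):
    hole_diameter: float
    max_residual: float


class SpanResult(NamedTuple):
    length: float
    extrapolated: bool


def _load_catalogue() -> pd.DataFrame:
    with importlib.resources.files("brimplan.data").joinpath("plates.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return df.set_index("manufacturer")


_BUILTIN_CACHE: SpanTable | None = None


def builtin_span_table() -> SpanTable:
    """The built-in four-manufacturer catalogue with its computed mean row.

    Column means are computed in exact decimal arithmetic and rounded
    half-up to 2 decimals (12.225 -> 12.23), matching how the catalogue's
    summary row is conventionally printed.  The returned table is a shared
    read-only instance.
    """
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is not None:
        return _BUILTIN_CACHE
    raw = _load_catalogue()
    cols = ["d", "e1", "e2", "e3", "e4"]
    dec = raw[cols].map(Decimal)
    mean_row = {
        col: float(round_half_up(sum(dec[col]) / Decimal(len(dec)), 2)) for col in cols
    }
    rows = raw[cols].astype(float)
    rows.loc[MEAN_LABEL] = [mean_row[c] for c in cols]
    _BUILTIN_CACHE = SpanTable(rows=rows)
    return _BUILTIN_CACHE


def mean_plate(hole_count: int = 10) -> PlateSpec:
    """The catalogue's mean plate (d = column-mean spacing)."""
    return builtin_span_table().plate(MEAN_LABEL, hole_count=hole_count)


def fit_hole_diameter(row) -> HoleDiameterFit:
    """Least-squares h in ``e_n = (n + 1) d - h`` for one catalogue row.

    With one free parameter the LS solution is the mean of (n+1)d - e_n;
    also reports the worst absolute residual of the fitted model.
    """
    d = float(row["d"])
    gaps = [(n + 1) * d - float(row[f"e{n}"]) for n in range(1, 5)]
    h = sum(gaps) / len(gaps)
    max_resid = max(abs(g - h) for g in gaps)
    return HoleDiameterFit(hole_diameter=h, max_residual=max_resid)


def span(plate: PlateSpec, n_vacant: int, table: SpanTable | None = None) -> SpanResult:
    """Span length across ``n_vacant`` consecutive vacant holes.

    Tabulated e_n is used when the plate is a catalogue row and n <= 4;
    otherwise the parametric model (n+1)*d - hole_diameter, flagged as
    extrapolated.
    """
    if n_vacant < 1:
        raise PlateError(f"n_vacant must be >= 1, got {n_vacant}")
    if table is None:
        table = builtin_span_table()
    if n_vacant <= 4 and plate.manufacturer in table.rows.index:
        return SpanResult(float(table.rows.loc[plate.manufacturer, f"e{n_vacant}"]), False)
    h = plate.hole_diameter if plate.hole_diameter is not None else DEFAULT_HOLE_DIAMETER
    return SpanResult((n_vacant + 1) * plate.d - h, True)


def span_length(plate: PlateSpec, n_vacant: int, table: SpanTable | None = None) -> float:
    """Convenience wrapper around :func:`span` returning just the length (mm)."""
    return span(plate, n_vacant, table).length
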