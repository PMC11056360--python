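"""Built-in study reference data: zone-length and brim-length summaries.

The four groups are male/female crossed with the side of the measured
hemi-pelvis (ML, MR, FL, FR).  Values are kept as exact decimal strings so
that derived report numbers (zone-mean sums, size-weighted sex means) can be
computed without binary-float rounding surprises; helpers return
:class:`decimal.Decimal` quantized with round-half-up, the convention used
for all reported means in this package.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: group sample sizes (subjects contribute one hemi-pelvis each)
REFERENCE_GROUP_SIZES = {"ML": 28, "MR": 17, "FL": 20, "FR": 15}

#: per-group zone-length (mean, SD) in mm, keyed a / b / c
REFERENCE_ZONES = {
    "ML": {"a": (Decimal("40.94"), Decimal("1.85")),
           "b": (Decimal("40.65"), Decimal("1.58")),
           "c": (Decimal("57.03"), Decimal("3.41"))},
    "MR": {"a": (Decimal("40.09"), Decimal("1.93")),
           "b": (Decimal("41.48"), Decimal("1.64")),
           "c": (Decimal("57.51"), Decimal("3.71"))},
    "FL": {"a": (Decimal("41.78"), Decimal("3.62")),
           "b": (Decimal("40.40"), Decimal("1.96")),
           "c": (Decimal("57.84"), Decimal("4.40"))},
    "FR": {"a": (Decimal("39.77"), Decimal("2.23")),
           "b": (Decimal("40.66"), Decimal("1.70")),
           "c": (Decimal("59.84"), Decimal("4.35"))},
}

#: per-group total brim length (mean, SD) in mm as reported
REFERENCE_BRIM = {
    "ML": (Decimal("138.63"), Decimal("4.29")),
    "MR": (Decimal("139.08"), Decimal("4.86")),
    "FL": (Decimal("140.02"), Decimal("8.44")),
    "FR": (Decimal("140.27"), Decimal("5.99")),
}

_SEX_GROUPS = {"male": ("ML", "MR"), "female": ("FL", "FR")}


def round_half_up(value, ndigits: int = 2) -> Decimal:
    """Round-half-up to ``ndigits`` decimals (12.225 -> 12.23).

    Floats are converted through ``str`` so a value that *prints* as the
    half-way case rounds the way a reader of the printed number expects.
    """
    if not isinstance(value, Decimal):
        value = Decimal(str(value))
    return value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)


def zone_mean_sum(group: str, ndigits: int = 2) -> Decimal:
    """Sum of the group's three zone means (should reproduce its brim mean)."""
    zones = REFERENCE_ZONES[group]
    return round_half_up(sum(zones[z][0] for z in ("a", "b", "c")), ndigits)


def sex_weighted_brim_mean(sex: str, ndigits: int = 2) -> Decimal:
    """Sample-size-weighted combination of the group brim means for one sex."""
    groups = _SEX_GROUPS[sex]
    total_n = sum(REFERENCE_GROUP_SIZES[g] for g in groups)
    weighted = sum(REFERENCE_BRIM[g][0] * REFERENCE_GROUP_SIZES[g] for g in groups)
    return round_half_up(weighted / Decimal(total_n), ndigits)
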