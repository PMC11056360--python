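"""Group summaries and hypothesis tests for zone-length cohorts.

Mirrors how such morphometric series are reported: per-group mean +- SD of
the three zone lengths and the total brim length, two-sample t tests between
paired groups (sides, sexes) and a one-way ANOVA across the four groups.
Subjects contribute one hemi-pelvis each, so all comparisons are unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import BrimplanError
from .reference import round_half_up

ZONE_COLUMNS = ("a", "b", "c")


class StatsError(BrimplanError, ValueError):
    """Degenerate statistical input."""


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD (mm) of the zones and the total brim length for one group.

    Values are kept unrounded; :meth:`rounded` renders the conventional
    2-decimal, round-half-up report figures.  SDs use the n-1 denominator
    (0.0 for a single subject).
    """

    group: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_c: float
    sd_c: float
    mean_total: float
    sd_total: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {"group": self.group, "n": self.n}
        for name in ("mean_a", "sd_a", "mean_b", "sd_b", "mean_c", "sd_c",
                     "mean_total", "sd_total"):
            out[name] = float(round_half_up(getattr(self, name), ndigits))
        return out


class TestResult(NamedTuple):
    statistic: float
    p_value: float


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_cohort(measurements: pd.DataFrame) -> list[GroupSummary]:
    """Per-group summaries from a table with columns group, a, b, c [, total].

    The total defaults to a + b + c.  Groups are summarized in sorted label
    order; an empty input raises :class:`StatsError`.
    """
    df = measurements.copy()
    missing = [c for c in ("group", *ZONE_COLUMNS) if c not in df.columns]
    if missing:
        raise StatsError(f"measurement table lacks columns {missing}")
    if len(df) == 0:
        raise StatsError("measurement table is empty")
    if "total" not in df.columns:
        df["total"] = df["a"] + df["b"] + df["c"]
    out = []
    for group, sub in df.groupby("group", sort=True):
        out.append(
            GroupSummary(
                group=str(group),
                n=len(sub),
                mean_a=float(sub["a"].mean()), sd_a=_sd(sub["a"].to_numpy()),
                mean_b=float(sub["b"].mean()), sd_b=_sd(sub["b"].to_numpy()),
                mean_c=float(sub["c"].mean()), sd_c=_sd(sub["c"].to_numpy()),
                mean_total=float(sub["total"].mean()), sd_total=_sd(sub["total"].to_numpy()),
            )
        )
    return out


def two_sample_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test; Student's pooled-variance form by default.

    Welch's unequal-variance form is available behind the ``welch`` flag.
    Requires n >= 2 per group and positive variance in at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise StatsError("both groups have zero variance")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(t), float(p))


def one_way_anova(*groups) -> TestResult:
    """Classical one-way ANOVA F test across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise StatsError("each group needs at least 2 observations")
    if all(np.var(g, ddof=1) == 0 for g in arrays):
        raise StatsError("zero within-group variance in every group")
    f, p = sps.f_oneway(*arrays)
    return TestResult(float(f), float(p))
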