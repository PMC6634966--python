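"""Quantification statistics behind imaging and organismal assays.

Published phenotype comparisons report percentages with sample sizes
(e.g. "9%, n = 206" vs "22% n = 406" methylation-accessible cells); this
module reconstructs the integer counts under explicit rounding assumptions,
runs an exact conditional (Fisher) test with the two-sided
point-probability rule, classifies lineage-tracing (G-TRACE) polyploid-cell
classes from their GFP/RFP flags, and summarizes survival tables with a
simple life table (fraction surviving past a horizon, median survival day
DT50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable:
    """2x2 group-by-outcome counts."""

    counts: np.ndarray
    group_labels: tuple = ("group1", "group2")
    outcome_labels: tuple = ("event", "no_event")

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("all-zero table")
        self.counts = c

    @classmethod
    def from_events(cls, events1: int, n1: int, events2: int, n2: int,
                    group_labels=("group1", "group2")) -> "ContingencyTable":
        return cls(
            np.array([[events1, n1 - events1], [events2, n2 - events2]]),
            group_labels=group_labels,
        )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float


def counts_from_percent(percent: float, n: int, rounding: str = "nearest",
                        decimals: int = 0):
    """Reconstruct integer event counts from a printed percentage.

    'nearest' returns round(percent * n / 100).  'all_consistent' returns
    every integer count whose percentage rounds (at ``decimals`` places,
    matching the printed precision) back to the printed value; an empty set
    means the printed numbers are mutually inconsistent.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if n <= 0:
        raise ValueError("n must be > 0")
    if rounding == "nearest":
        return int(round(percent * n / 100.0))
    if rounding == "all_consistent":
        target = round(percent, decimals)
        return [c for c in range(n + 1) if round(100.0 * c / n, decimals) == target]
    raise ValueError("rounding must be 'nearest' or 'all_consistent'")


def fisher_exact(table: ContingencyTable) -> FisherResult:
    """Exact conditional test for a 2x2 table.

    Two-sided p sums the probabilities of every table with the observed
    margins whose point probability does not exceed the observed table's
    (with a small relative tolerance against float ties).  Odds ratio is
    (a*d)/(b*c); 0/0 is reported as NaN.
    """
    a, b = int(table.counts[0, 0]), int(table.counts[0, 1])
    c, d = int(table.counts[1, 0]), int(table.counts[1, 1])
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    num, den = a * d, b * c
    if den == 0:
        odds = math.nan if num == 0 else math.inf
    else:
        odds = num / den
    return FisherResult(odds_ratio=odds, p_value=p)


GTRACE_CLASSES = {
    "EC": (True, True),       # history and current marker: differentiated EC
    "PPC**": (True, False),   # lost current marker: former EC, identity lost
    "PPC*": (False, False),   # neither marker: mis-differentiated newcomer
    "PPC^R": (False, True),   # current without history: missed recombination
}


def classify_gtrace(cells: pd.DataFrame) -> dict[str, float]:
    """Fractions of polyploid cells in the four lineage-tracing classes.

    ``cells`` needs boolean columns gfp (history marker), rfp (current
    marker) and polyploid; non-polyploid cells are excluded.  Fractions sum
    to 1 over polyploid cells.
    """
    if cells.empty:
        raise ValueError("empty cell table")
    for col in ("gfp", "rfp", "polyploid"):
        if col not in cells.columns:
            raise ValueError(f"cell table missing column {col!r}")
    poly = cells[cells["polyploid"].astype(bool)]
    if poly.empty:
        raise ValueError("no polyploid cells to classify")
    n = len(poly)
    out = {}
    for label, (gfp, rfp) in GTRACE_CLASSES.items():
        mask = (poly["gfp"].astype(bool) == gfp) & (poly["rfp"].astype(bool) == rfp)
        out[label] = float(mask.sum()) / n
    return out


def survival_summary(table: pd.DataFrame, horizon_day: int) -> pd.DataFrame:
    """Per-group life-table summary: fraction surviving past a horizon and
    DT50 (first day cumulative deaths reach 50% of the starting cohort).

    ``table`` has one row per individual: group, day, censored.  Censored
    individuals count as alive through their censor day and leave the
    denominator afterwards (simple life table, product-limit over whole
    days).  A horizon before the first event gives fraction 1.0.
    """
    for col in ("group", "day", "censored"):
        if col not in table.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (table["day"] <= 0).any():
        raise ValueError("days must be > 0")
    rows = []
    for group, grp in table.groupby("group", sort=False):
        n0 = len(grp)
        at_risk = n0
        surv = 1.0
        cum_deaths = 0
        dt50 = math.nan
        for day in sorted(grp["day"].unique()):
            deaths = int(((grp["day"] == day) & ~grp["censored"]).sum())
            censored = int(((grp["day"] == day) & grp["censored"]).sum())
            if day <= horizon_day and at_risk > 0:
                surv *= 1.0 - deaths / at_risk
            cum_deaths += deaths
            if math.isnan(dt50) and cum_deaths >= 0.5 * n0:
                dt50 = day
            at_risk -= deaths + censored
        rows.append(
            {
                "group": group,
                "n": n0,
                "fraction_surviving": surv,
                "dt50": dt50,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "fraction_surviving", "dt50"])
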