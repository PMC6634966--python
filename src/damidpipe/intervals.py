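"""Genomic interval arithmetic: overlap, 80%-rule domain-set matching, gene assignment.

All coordinates are 0-based half-open; an ``IntervalSet`` is a validated,
per-chromosome-sorted table of records of one kind (domain, peak, gene or
chromatin state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
VALID_STRANDS = {"+", "-"}


@dataclass
class IntervalSet:
    """Typed set of genomic intervals in 0-based half-open coordinates.

    ``records`` carries at least chrom/start/end/name; score holds the mean
    normalized log2 ratio for domains and peaks, and strand is meaningful
    for genes only.
    """

    records: pd.DataFrame
    kind: str = "domain"

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        for col in ("chrom", "start", "end", "name"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet records missing column {col!r}")
        if "score" not in df.columns:
            df["score"] = 0.0
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"interval with start >= end: {bad['name']}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def assert_disjoint(self) -> None:
        """Raise if any two intervals within the set overlap."""
        for chrom, grp in self.records.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = bad[0]
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"{grp['name'].iloc[i]} and {grp['name'].iloc[i + 1]}"
                )

    @classmethod
    def from_bed(cls, path: str | Path, kind: str = "domain") -> "IntervalSet":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=BED_COLUMNS)
        df.columns = BED_COLUMNS[: df.shape[1]]
        return cls(df, kind=kind)

    def to_bed(self, path: str | Path) -> None:
        df = self.records.copy()
        cols = [c for c in BED_COLUMNS if c in df.columns]
        df[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class OverlapParams:
    """Parameters of the minimum-overlap rule used to compare domain sets.

    mode="either" matches the published rule: a pair overlaps if at least
    one of the two domains is covered >= min_fraction by the intersection.
    """

    min_fraction: float = 0.80
    mode: str = "either"

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.mode not in ("either", "reciprocal"):
            raise ValueError("mode must be 'either' or 'reciprocal'")


@dataclass(frozen=True)
class GeneAssignmentParams:
    """How a binding domain is mapped to genes: gene body plus a strand-aware
    upstream promoter window (and an optional downstream window)."""

    upstream_window: int = 2000
    downstream_window: int = 0
    use_gene_body: bool = True

    def __post_init__(self) -> None:
        if self.upstream_window < 0 or self.downstream_window < 0:
            raise ValueError("windows must be >= 0")


def overlap_length(a: tuple, b: tuple) -> int:
    """Length of the intersection of two half-open intervals (chrom, start, end).

    Different chromosomes overlap by 0 bp by contract.
    """
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


@dataclass
class MatchResult:
    matches: pd.DataFrame  # columns: name_a, name_b, overlap_bp, frac_a, frac_b
    a_only: list = field(default_factory=list)
    b_only: list = field(default_factory=list)


def match_domain_sets(
    set_a: IntervalSet, set_b: IntervalSet, params: OverlapParams | None = None
) -> MatchResult:
    """One-to-one matching of two domain sets under a minimum-overlap rule.

    A candidate pair passes when overlap/len exceeds ``min_fraction`` for at
    least one member (mode="either") or for both (mode="reciprocal").
    Passing pairs are matched greedily by largest overlap, ties broken toward
    the leftmost pair, and each domain is used at most once.
    """
    params = params or OverlapParams()
    set_a.assert_disjoint()
    set_b.assert_disjoint()
    a = set_a.records
    b = set_b.records

    candidates = []
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        for ia, ra in ga.iterrows():
            ov = np.minimum(gb["end"].to_numpy(), ra["end"]) - np.maximum(
                gb["start"].to_numpy(), ra["start"]
            )
            hit = np.nonzero(ov > 0)[0]
            for j in hit:
                ib = gb.index[j]
                o = int(ov[j])
                fa = o / (ra["end"] - ra["start"])
                fb = o / (gb["end"].iloc[j] - gb["start"].iloc[j])
                ok = (
                    max(fa, fb) >= params.min_fraction
                    if params.mode == "either"
                    else min(fa, fb) >= params.min_fraction
                )
                if ok:
                    candidates.append((o, ia, ib, fa, fb))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    rows = []
    for o, ia, ib, fa, fb in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append(
            {
                "name_a": a.loc[ia, "name"],
                "name_b": b.loc[ib, "name"],
                "overlap_bp": o,
                "frac_a": fa,
                "frac_b": fb,
            }
        )
    matches = pd.DataFrame(rows, columns=["name_a", "name_b", "overlap_bp", "frac_a", "frac_b"])
    a_only = [n for i, n in zip(a.index, a["name"]) if i not in used_a]
    b_only = [n for i, n in zip(b.index, b["name"]) if i not in used_b]
    return MatchResult(matches=matches, a_only=a_only, b_only=b_only)


def _gene_windows(row: pd.Series, params: GeneAssignmentParams) -> list[tuple[int, int]]:
    """Half-open intervals scanned for binding: body and strand-aware flanks."""
    strand = row.get("strand", "+")
    if strand not in VALID_STRANDS:
        raise ValueError(f"unknown strand symbol {strand!r} for gene {row['name']}")
    start, end = int(row["start"]), int(row["end"])
    windows = []
    if params.use_gene_body:
        windows.append((start, end))
    if params.upstream_window:
        if strand == "+":
            windows.append((max(0, start - params.upstream_window), start))
        else:
            windows.append((end, end + params.upstream_window))
    if params.downstream_window:
        if strand == "+":
            windows.append((end, end + params.downstream_window))
        else:
            windows.append((max(0, start - params.downstream_window), start))
    return [(s, e) for s, e in windows if e > s]


def assign_domains_to_genes(
    domains: IntervalSet,
    genes: IntervalSet,
    params: GeneAssignmentParams | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag each gene as bound when any domain overlaps (>= 1 bp) its body or
    strand-aware upstream window.

    Returns a boolean Series indexed by gene name and a table of
    (domain, gene) incidences.
    """
    params = params or GeneAssignmentParams()
    dom = domains.records
    bound = pd.Series(False, index=genes.records["name"], name="bound")
    pairs = []
    for _, g in genes.records.iterrows():
        gdom = dom[dom["chrom"] == g["chrom"]]
        if gdom.empty:
            continue
        for s, e in _gene_windows(g, params):
            ov = np.minimum(gdom["end"].to_numpy(), e) - np.maximum(gdom["start"].to_numpy(), s)
            hit = np.nonzero(ov > 0)[0]
            if hit.size:
                bound[g["name"]] = True
                for j in hit:
                    pairs.append({"domain": gdom["name"].iloc[j], "gene": g["name"]})
    pair_df = pd.DataFrame(pairs, columns=["domain", "gene"]).drop_duplicates().reset_index(drop=True)
    return bound, pair_df
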