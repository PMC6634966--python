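"""Integration of binding calls with differential expression.

Covers the Venn-style questions asked of a binding map and a DEG list:
how large is the overlap and is it surprising (hypergeometric upper tail
over a finite gene universe), what fraction of bound-and-regulated genes
require the factor for their expression (direction of regulation upon
knockdown), and which DEGs are putative direct targets (bound DEGs).

The gene universe is the annotation the analysis ran on, not the genome;
every report states it, because enrichment p-values are meaningless
without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class GeneSetComparison:
    """Overlap of two gene sets drawn from a universe of N genes."""

    N: int
    nA: int
    nB: int
    k: int
    p_value: float
    fold_enrichment: float
    expected: float


@dataclass(frozen=True)
class DirectionFractions:
    """Of bound-and-regulated genes, the split by response to knockdown.

    frac_activated: fraction going down upon knockdown (the factor was
    required for their expression); frac_repressed: fraction going up.
    ``defined`` is False when no gene is both bound and regulated.
    """

    n: int
    frac_activated: float
    frac_repressed: float
    defined: bool


@dataclass(frozen=True)
class DirectTargets:
    genes: tuple
    n_deg: int
    n_bound_deg: int
    fraction: float


def hypergeometric_overlap(nA: int, nB: int, k: int, N: int) -> GeneSetComparison:
    """Upper-tail hypergeometric test P(X >= k), X ~ Hypergeom(N, nA, nB).

    Summed in log space for stability at extreme overlaps.
    """
    if min(nA, nB, k, N) < 0:
        raise ValueError("counts must be non-negative")
    if nA > N or nB > N:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(nA, nB):
        raise ValueError(f"overlap k={k} exceeds min(nA, nB)={min(nA, nB)}")
    if k == 0:
        p = 1.0
    else:
        js = np.arange(k, min(nA, nB) + 1)
        logp = stats.hypergeom.logpmf(js, N, nA, nB)
        p = float(min(1.0, np.exp(logsumexp(logp))))
    expected = nA * nB / N if N else float("nan")
    fold = k / expected if expected > 0 else float("nan")
    return GeneSetComparison(
        N=N, nA=nA, nB=nB, k=k, p_value=p, fold_enrichment=fold, expected=expected
    )


def direction_fractions(deg_table: pd.DataFrame, bound: pd.Series) -> DirectionFractions:
    """Split of bound, filter-passing DEGs by direction of change.

    ``bound`` is a boolean Series indexed like ``deg_table`` (missing genes
    count as unbound).
    """
    flags = bound.reindex(deg_table.index).fillna(False).astype(bool)
    sel = deg_table[deg_table["passes_filter"] & flags]
    n = len(sel)
    if n == 0:
        return DirectionFractions(n=0, frac_activated=float("nan"),
                                  frac_repressed=float("nan"), defined=False)
    down = float((sel["log2fc"] < 0).sum()) / n
    return DirectionFractions(n=n, frac_activated=down, frac_repressed=1.0 - down, defined=True)


def putative_direct_targets(deg_list, bound_genes) -> DirectTargets:
    """Bound DEGs (set intersection) and the bound fraction of the DEG list.

    The fraction is reported as exact arithmetic; rounded percentages in
    summaries elsewhere can disagree with it at the last digit.
    """
    degs = list(deg_list)
    if len(set(degs)) != len(degs):
        raise ValueError("duplicate gene ids in deg_list")
    bound = set(bound_genes)
    inter = sorted(g for g in degs if g in bound)
    frac = len(inter) / len(degs) if degs else 0.0
    return DirectTargets(
        genes=tuple(inter), n_deg=len(degs), n_bound_deg=len(inter), fraction=frac
    )


def three_way_table(deg_list, bound_genes, universe_size: int) -> dict:
    """Bound-only / regulated-only / both counts plus the enrichment test."""
    degs = set(deg_list)
    bound = set(bound_genes)
    k = len(degs & bound)
    comparison = hypergeometric_overlap(len(bound), len(degs), k, universe_size)
    return {
        "universe": universe_size,
        "bound_only": len(bound - degs),
        "regulated_only": len(degs - bound),
        "both": k,
        "hypergeometric_p": comparison.p_value,
        "fold_enrichment": comparison.fold_enrichment,
    }
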