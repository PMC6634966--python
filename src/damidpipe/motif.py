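"""Degenerate-motif scanning and enrichment against random background.

The default pattern is the E-box CANNTG, the binding site of bHLH
transcription factors of the HES/Hey family;
it is reverse-complement symmetric, so forward-strand counting is already
complete for it.  Enrichment is the per-kb motif density of the foreground
over the background, with an empirical p-value from permuting the
foreground/background labels (the published E-value came from an external
motif tool whose background model is not reproducible here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import stage_rng

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
SEQUENCE_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MotifParams:
    """pattern is an IUPAC string; count_mode both_strands_dedup counts
    positions matching the pattern on either strand once (identical to
    forward_only for palindromic patterns)."""

    pattern: str = "CANNTG"
    n_background: int = 6000
    background_length_range: tuple[int, int] = (2000, 5000)
    n_permutations: int = 1000
    count_mode: str = "forward_only"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {bad}")
        if self.n_background <= 0 or self.n_permutations <= 0:
            raise ValueError("counts must be > 0")
        if self.count_mode not in ("forward_only", "both_strands_dedup"):
            raise ValueError("count_mode must be forward_only or both_strands_dedup")


@dataclass(frozen=True)
class MotifResult:
    foreground_density: float  # occurrences per kb
    background_density: float
    enrichment: float
    p_value: float
    n_foreground: int
    n_background: int


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all counted
    body = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
    return re.compile(f"(?=({body}))")


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(COMPLEMENT)[::-1]


def _as_pairs(sequences) -> list[tuple[str, str]]:
    pairs = []
    for i, rec in enumerate(sequences):
        if hasattr(rec, "seq"):
            pairs.append((rec.id or f"seq{i}", str(rec.seq)))
        elif isinstance(rec, tuple):
            pairs.append((rec[0], rec[1]))
        else:
            pairs.append((f"seq{i}", str(rec)))
    return pairs


def scan_motif(sequences, params: MotifParams | None = None) -> pd.DataFrame:
    """Count motif occurrences per sequence (overlaps included).

    Sequences must be over A/C/G/T/N (case-insensitive); an N in the
    sequence matches nothing.  Raises at the first non-IUPAC input
    character.  Returns a frame with seq_id, length, count.
    """
    params = params or MotifParams()
    fwd = _pattern_regex(params.pattern)
    rev_pat = reverse_complement(params.pattern)
    rev = _pattern_regex(rev_pat) if params.count_mode == "both_strands_dedup" else None
    rows = []
    for seq_id, raw in _as_pairs(sequences):
        seq = raw.upper()
        for pos, ch in enumerate(seq):
            if ch not in SEQUENCE_ALPHABET:
                raise ValueError(f"non-IUPAC character {ch!r} in {seq_id} at position {pos}")
        positions = {m.start() for m in fwd.finditer(seq)}
        if rev is not None and rev_pat != params.pattern.upper():
            positions |= {m.start() for m in rev.finditer(seq)}
        rows.append({"seq_id": seq_id, "length": len(seq), "count": len(positions)})
    return pd.DataFrame(rows, columns=["seq_id", "length", "count"])


def motif_enrichment(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    params: MotifParams | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> MotifResult:
    """Density ratio of foreground over background with a permutation p.

    Inputs are scan_motif tables (length, count per sequence).  The
    empirical p is (1 + #{label permutations with ratio >= observed}) /
    (n_permutations + 1), so it is never below 1/(n_permutations + 1).
    """
    params = params or MotifParams()
    if foreground.empty or background.empty:
        raise ValueError("foreground and background must be non-empty")
    rng = rng if rng is not None else stage_rng(seed, "motif_enrichment")
    counts = np.concatenate(
        [foreground["count"].to_numpy(float), background["count"].to_numpy(float)]
    )
    lengths = np.concatenate(
        [foreground["length"].to_numpy(float), background["length"].to_numpy(float)]
    )
    n_fg = len(foreground)
    fg_density = 1000.0 * counts[:n_fg].sum() / lengths[:n_fg].sum()
    bg_density = 1000.0 * counts[n_fg:].sum() / lengths[n_fg:].sum()
    if bg_density == 0:
        raise ValueError("background motif density is zero; enrichment undefined")
    observed = fg_density / bg_density

    n_total = counts.size
    hits = 0
    for _ in range(params.n_permutations):
        perm = rng.permutation(n_total)
        f = perm[:n_fg]
        b = perm[n_fg:]
        num = counts[f].sum() / lengths[f].sum()
        den = counts[b].sum() / lengths[b].sum()
        ratio = np.inf if den == 0 else num / den
        if ratio >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (params.n_permutations + 1)
    return MotifResult(
        foreground_density=fg_density,
        background_density=bg_density,
        enrichment=observed,
        p_value=p,
        n_foreground=n_fg,
        n_background=len(background),
    )
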