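"""Synthetic inputs with planted ground truth.

Emulates a NimbleGen-style tiling-array design (~300 bp probe spacing, two
biological replicates plus a dye-swap technical replicate), planting broad
enriched domains on a log2-ratio track, a gene annotation with a configurable
fraction of domains linked to genes, expression matrices with 2-fold-or-
greater planted effects on linked genes, random background sequences, and
phenotype count/survival fixtures.  Every generator is fully deterministic
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import stage_rng
from .arrays import ArraySample
from .intervals import IntervalSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Array geometry follows the emulated design (probe spacing ~300 bp, two
    biological replicates plus one dye swap).  Domains are planted on the
    log2-ratio scale (domain_effect, in log2 units) and converted to channel
    intensities around a fixed baseline so the LOESS-removable intensity bias
    (intensity_bias_amplitude) and the biological effect are independently
    controllable.  Domains snap to probe boundaries, keep
    ``min_domain_gap_probes`` clearance from each other and
    ``edge_margin_probes`` from chromosome ends, which makes exact recovery
    by a 199-probe edge filter well-defined.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    probe_spacing: int = 300
    probe_length: int = 50
    n_domains: int = 50
    domain_length_range: tuple[int, int] = (15_000, 60_000)
    domain_effect: float = 1.0
    n_peaks: int = 20
    peak_effect: float = 2.0
    peak_width_probes: tuple[int, int] = (1, 3)
    noise_sd: float = 0.25
    intensity_bias_amplitude: float = 0.5
    baseline_log2_intensity: float = 10.0
    abundance_sd: float = 1.0
    n_biological_replicates: int = 2
    include_dye_swap: bool = True
    min_domain_gap_probes: int = 210
    edge_margin_probes: int = 110
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    frac_genes_linked: float = 0.8
    frac_linked_activated: float = 0.7
    n_indirect_de: int = 80
    de_fold_change: float = 2.0
    expr_noise_sd: float = 0.25
    n_expr_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors = []
        if self.probe_spacing <= 0:
            errors.append("probe_spacing must be > 0")
        if not 0 < self.probe_length <= self.probe_spacing:
            errors.append("probe_length must be in (0, probe_spacing]")
        if self.domain_length_range[0] < 2 * self.probe_spacing:
            errors.append("domain lengths must be >= 2 * probe_spacing")
        if self.domain_length_range[0] > self.domain_length_range[1]:
            errors.append("domain_length_range must be (low, high) with low <= high")
        for name in ("frac_genes_linked", "frac_linked_activated"):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            errors.append("noise_sd must be >= 0")
        if self.expr_noise_sd < 0:
            errors.append("expr_noise_sd must be >= 0")
        if self.de_fold_change < 1:
            errors.append("de_fold_change must be >= 1")
        if self.n_expr_replicates < 2:
            errors.append("n_expr_replicates must be >= 2 (variance undefined below)")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class TruthSet:
    """Planted ground truth: domains with effects, signed DE genes, and the
    domain-to-gene linkage used by recovery tests."""

    true_domains: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "name", "effect", "i_start", "i_end"]
        )
    )
    true_peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "name", "effect", "i_start", "i_end"]
        )
    )
    true_de_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "log2fc", "linked_domain"])
    )
    domain_gene_links: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["domain", "gene"])
    )


def make_probe_grid(config: SyntheticConfig) -> pd.DataFrame:
    """Tile each chromosome with fixed-spacing probes (0-based half-open).

    A chromosome shorter than one spacing gets zero probes, with a warning.
    """
    config.validate()
    frames = []
    counter = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        n = config.chromosome_length // config.probe_spacing
        if n == 0:
            warnings.warn(f"{chrom} shorter than one probe spacing; no probes", stacklevel=2)
            continue
        starts = np.arange(n, dtype=np.int64) * config.probe_spacing
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + config.probe_length,
                    "probe_id": [f"p{counter + i:07d}" for i in range(n)],
                }
            )
        )
        counter += n
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "probe_id"])
    return pd.concat(frames, ignore_index=True)


def plant_domains(config: SyntheticConfig, grid: pd.DataFrame) -> TruthSet:
    """Place ``n_domains`` disjoint domains snapped to probe boundaries.

    Domain intervals run from the start of their first probe to the end of
    their last probe.  Placement keeps a clearance of
    ``min_domain_gap_probes`` between domains and ``edge_margin_probes`` from
    chromosome ends; a bounded number of rejection-sampling retries is used
    and failure reports the achieved count.
    """
    config.validate()
    if config.n_domains == 0 and config.n_peaks == 0:
        return TruthSet()
    if grid.empty:
        raise ValueError("cannot plant domains on an empty probe grid")
    rng = stage_rng(config.seed, "plant_domains")
    chrom_groups = {c: g.reset_index(drop=True) for c, g in grid.groupby("chrom", sort=False)}
    chroms = list(chrom_groups)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    max_attempts = 200 * config.n_domains
    gap = config.min_domain_gap_probes
    margin = config.edge_margin_probes
    while len(rows) < config.n_domains and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        g = chrom_groups[chrom]
        length = int(rng.integers(config.domain_length_range[0], config.domain_length_range[1] + 1))
        n_probes = max(2, int(round(length / config.probe_spacing)))
        lo, hi = margin, len(g) - margin - n_probes
        if hi <= lo:
            continue
        i0 = int(rng.integers(lo, hi))
        i1 = i0 + n_probes - 1
        if any(i0 - gap <= e and i1 + gap >= s for s, e in placed[chrom]):
            continue
        placed[chrom].append((i0, i1))
        rows.append(
            {
                "chrom": chrom,
                "start": int(g["start"].iloc[i0]),
                "end": int(g["end"].iloc[i1]),
                "name": f"dom{len(rows):04d}",
                "effect": config.domain_effect,
                "i_start": i0,
                "i_end": i1,
            }
        )
    if len(rows) < config.n_domains:
        raise ValueError(
            f"could only place {len(rows)} of {config.n_domains} domains without overlap"
        )
    if rows:
        domains = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        domains["name"] = [f"dom{i:04d}" for i in range(len(domains))]
    else:
        domains = TruthSet().true_domains

    # single peaks: short spikes well clear of domains and of each other
    peak_rows: list[dict] = []
    peak_gap = 20
    attempts = 0
    max_attempts = 200 * max(1, config.n_peaks)
    while len(peak_rows) < config.n_peaks and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        g = chrom_groups[chrom]
        width = int(rng.integers(config.peak_width_probes[0], config.peak_width_probes[1] + 1))
        lo, hi = margin, len(g) - margin - width
        if hi <= lo:
            continue
        i0 = int(rng.integers(lo, hi))
        i1 = i0 + width - 1
        taken = placed[chrom] + [
            (p["i_start"], p["i_end"]) for p in peak_rows if p["chrom"] == chrom
        ]
        if any(i0 - peak_gap <= e and i1 + peak_gap >= s for s, e in taken):
            continue
        peak_rows.append(
            {
                "chrom": chrom,
                "start": int(g["start"].iloc[i0]),
                "end": int(g["end"].iloc[i1]),
                "name": f"pk{len(peak_rows):04d}",
                "effect": config.peak_effect,
                "i_start": i0,
                "i_end": i1,
            }
        )
    if len(peak_rows) < config.n_peaks:
        raise ValueError(
            f"could only place {len(peak_rows)} of {config.n_peaks} peaks without overlap"
        )
    peaks = (
        pd.DataFrame(peak_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        if peak_rows
        else TruthSet().true_peaks
    )
    if len(peaks):
        peaks["name"] = [f"pk{i:04d}" for i in range(len(peaks))]
    return TruthSet(true_domains=domains, true_peaks=peaks)


def domain_probe_mask(grid: pd.DataFrame, domains: pd.DataFrame) -> np.ndarray:
    """Boolean mask over grid rows: probe fully inside a planted domain."""
    mask = np.zeros(len(grid), dtype=bool)
    starts = grid["start"].to_numpy()
    ends = grid["end"].to_numpy()
    chroms = grid["chrom"].to_numpy()
    for _, d in domains.iterrows():
        mask |= (chroms == d["chrom"]) & (starts >= d["start"]) & (ends <= d["end"])
    return mask


def simulate_damid_arrays(
    config: SyntheticConfig, grid: pd.DataFrame, truth: TruthSet
) -> list[ArraySample]:
    """Simulate fusion/control channel intensities for every replicate.

    The expected log2(fusion/control) equals ``domain_effect`` inside planted
    domains and 0 outside, plus Gaussian noise (``noise_sd``) and a smooth
    intensity-dependent dye bias of amplitude ``intensity_bias_amplitude``
    that LOESS must remove.  The effect is split symmetrically across the
    two channels so probe mean intensity A is independent of domain
    membership.  The dye-swap replicate has its physical channels exchanged.
    """
    config.validate()
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = stage_rng(config.seed, "simulate_damid_arrays")
    in_domain = domain_probe_mask(grid, truth.true_domains)
    in_peak = domain_probe_mask(grid, truth.true_peaks)
    n = len(grid)
    abundance = config.baseline_log2_intensity + config.abundance_sd * rng.standard_normal(n)
    dye_bias = config.intensity_bias_amplitude * np.tanh(
        abundance - config.baseline_log2_intensity
    )
    m_true = np.where(in_domain, config.domain_effect, 0.0)
    m_true = np.where(in_peak, config.peak_effect, m_true)

    samples = []
    reps = [(f"rep{i + 1}", False) for i in range(config.n_biological_replicates)]
    if config.include_dye_swap:
        reps.append(("rep1_dyeswap", True))
    for sample_id, swapped in reps:
        noise = config.noise_sd * rng.standard_normal(n)
        biological = m_true + noise
        # dye bias stays with the physical dyes, so it adds after the swap
        m_phys = (-biological if swapped else biological) + dye_bias
        fusion = np.exp2(abundance + 0.5 * m_phys)
        control = np.exp2(abundance - 0.5 * m_phys)
        df = grid.copy()
        df["intensity_fusion"] = fusion
        df["intensity_control"] = control
        samples.append(ArraySample(sample_id=sample_id, dye_swapped=swapped, probes=df))
    return samples


def plant_genes(
    config: SyntheticConfig, grid: pd.DataFrame, truth: TruthSet
) -> tuple[IntervalSet, TruthSet]:
    """Place a stranded gene annotation and define the planted DE genes.

    round(frac_genes_linked * n_domains) domains each get one gene whose
    body starts inside the domain (a direct target, DE with sign set by
    ``frac_linked_activated``: activated targets lose expression upon
    knockdown, i.e. negative log2 fold change).  ``n_indirect_de`` further
    DE genes and all remaining genes are placed clear of every domain
    (3 kb buffer) so indirect DE genes are never bound.
    """
    config.validate()
    rng = stage_rng(config.seed, "plant_genes")
    domains = truth.true_domains
    chrom_groups = {c: g.reset_index(drop=True) for c, g in grid.groupby("chrom", sort=False)}
    chroms = list(chrom_groups)
    chrom_len = {c: int(g["end"].iloc[-1]) for c, g in chrom_groups.items()}

    n_linked = int(round(config.frac_genes_linked * len(domains)))
    linked_domains = domains.iloc[
        sorted(rng.choice(len(domains), size=n_linked, replace=False))
    ] if n_linked else domains.iloc[:0]

    rows = []
    links = []
    gi = 0
    for _, d in linked_domains.iterrows():
        length = int(rng.integers(*config.gene_length_range))
        start = int(d["start"]) + int(
            rng.integers(0, max(1, (d["end"] - d["start"]) // 2))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"g{gi:05d}"
        rows.append(
            {
                "chrom": d["chrom"],
                "start": start,
                "end": start + length,
                "name": name,
                "score": 0.0,
                "strand": strand,
            }
        )
        links.append({"domain": d["name"], "gene": name})
        gi += 1

    # exclusion zones: domains padded by 3 kb so unlinked genes are unbound
    buffer = 3000
    zones = {c: [] for c in chroms}
    for _, d in domains.iterrows():
        zones[d["chrom"]].append((d["start"] - buffer, d["end"] + buffer))
    occupied = {c: [] for c in chroms}
    for r in rows:
        occupied[r["chrom"]].append((r["start"], r["end"]))

    n_rest = config.n_genes - gi
    attempts = 0
    max_attempts = 400 * max(1, n_rest)
    while gi - len(links) < n_rest and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.gene_length_range))
        start = int(rng.integers(0, max(1, chrom_len[chrom] - length)))
        end = start + length
        if any(start < e and end > s for s, e in zones[chrom]):
            continue
        if any(start - 500 < e and end + 500 > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": f"g{gi:05d}",
                "score": 0.0,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        gi += 1
    if gi < config.n_genes:
        raise ValueError(f"could only place {gi} of {config.n_genes} genes")

    genes = IntervalSet(pd.DataFrame(rows), kind="gene")
    linked_names = [l["gene"] for l in links]
    lfc = np.log2(config.de_fold_change)
    de_rows = []
    for name in linked_names:
        activated = rng.random() < config.frac_linked_activated
        de_rows.append(
            {
                "gene": name,
                "log2fc": -lfc if activated else lfc,
                "linked_domain": next(l["domain"] for l in links if l["gene"] == name),
            }
        )
    unlinked_names = [r["name"] for r in rows if r["name"] not in set(linked_names)]
    n_indirect = min(config.n_indirect_de, len(unlinked_names))
    for name in rng.choice(unlinked_names, size=n_indirect, replace=False):
        de_rows.append(
            {"gene": name, "log2fc": lfc if rng.random() < 0.5 else -lfc, "linked_domain": None}
        )
    truth_out = TruthSet(
        true_domains=truth.true_domains,
        true_peaks=truth.true_peaks,
        true_de_genes=pd.DataFrame(de_rows, columns=["gene", "log2fc", "linked_domain"]),
        domain_gene_links=pd.DataFrame(links, columns=["domain", "gene"]),
    )
    return genes, truth_out


def simulate_expression_matrix(
    gene_ids: list[str],
    log2fc: dict[str, float],
    noise_sd: float,
    n_replicates: int,
    rng: np.random.Generator,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Low-level log-scale expression simulator shared by the benchmark and
    the calibration suites.  Returns (matrix genes x samples, group labels)."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group (variance undefined)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_genes = len(gene_ids)
    base = baseline_mean + baseline_sd * rng.standard_normal(n_genes)
    shift = np.array([log2fc.get(g, 0.0) for g in gene_ids])
    cols = {}
    groups = {}
    for i in range(n_replicates):
        name = f"control_{i + 1}"
        cols[name] = base + noise_sd * rng.standard_normal(n_genes)
        groups[name] = "control"
    for i in range(n_replicates):
        name = f"knockdown_{i + 1}"
        cols[name] = base + shift + noise_sd * rng.standard_normal(n_genes)
        groups[name] = "knockdown"
    matrix = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    return matrix, pd.Series(groups, name="group")


def simulate_expression(
    config: SyntheticConfig, truth: TruthSet, genes: IntervalSet
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group (control vs knockdown) log-scale matrix over the annotation,
    with planted genes shifted by log2(de_fold_change) with their stated sign."""
    config.validate()
    if len(genes) == 0:
        raise ValueError("gene annotation is empty")
    rng = stage_rng(config.seed, "simulate_expression")
    lfc = dict(zip(truth.true_de_genes["gene"], truth.true_de_genes["log2fc"]))
    return simulate_expression_matrix(
        list(genes.records["name"]),
        lfc,
        config.expr_noise_sd,
        config.n_expr_replicates,
        rng,
    )


def simulate_background_sequences(
    n: int,
    length_range: tuple[int, int] = (2000, 5000),
    gc: float = 0.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[SeqRecord]:
    """n i.i.d. random sequences, lengths uniform on the range, base
    composition matching the requested GC fraction (default 0.5)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if length_range[0] < 2 or length_range[0] > length_range[1]:
        raise ValueError("invalid length_range")
    rng = rng if rng is not None else stage_rng(seed, "background_sequences")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(bases[rng.choice(4, size=length, p=probs)])
        records.append(SeqRecord(Seq(seq), id=f"bg{i:05d}", description=""))
    return records


def simulate_motif_enriched_sequences(
    n: int,
    length_range: tuple[int, int],
    motif: str,
    per_kb: float,
    gc: float = 0.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[SeqRecord]:
    """Random sequences with exact motif instances planted at ~per_kb
    Poisson density (non-overlapping insertion positions), emulating bound
    regions enriched for a binding site."""
    rng = rng if rng is not None else stage_rng(seed, "motif_sequences")
    records = simulate_background_sequences(n, length_range, gc=gc, rng=rng)
    k = len(motif)
    out = []
    for i, rec in enumerate(records):
        seq = list(str(rec.seq))
        n_insert = rng.poisson(per_kb * len(seq) / 1000)
        if n_insert:
            slots = np.arange(0, max(1, len(seq) - k), k)
            chosen = rng.choice(slots, size=min(n_insert, len(slots)), replace=False)
            for pos in chosen:
                seq[pos : pos + k] = motif
        out.append(SeqRecord(Seq("".join(seq)), id=f"fg{i:05d}", description=""))
    return out


def simulate_phenotype_counts(
    spec: list[tuple[str, int, float]], seed: int = 0
) -> pd.DataFrame:
    """Binomial event counts per group: rows (group, n, events)."""
    rng = stage_rng(seed, "phenotype_counts")
    rows = []
    for group, n, p in spec:
        if n < 0:
            raise ValueError("n must be >= 0")
        if not 0 <= p <= 1:
            raise ValueError("event probability must be in [0, 1]")
        rows.append({"group": group, "n": n, "events": int(rng.binomial(n, p))})
    return pd.DataFrame(rows)


def simulate_survival_table(
    spec: list[tuple[str, int, float, float]], seed: int = 0
) -> pd.DataFrame:
    """Per-individual death days, one row per fly: (group, day, censored).

    Death days are drawn from a truncated normal (mean, sd per group),
    rounded to whole days with a floor of day 1; no censoring is generated.
    """
    rng = stage_rng(seed, "survival")
    rows = []
    for group, n, mean_day, sd_day in spec:
        if n < 0:
            raise ValueError("n must be >= 0")
        days = np.maximum(1, np.round(mean_day + sd_day * rng.standard_normal(n))).astype(int)
        for d in days:
            rows.append({"group": group, "day": int(d), "censored": False})
    return pd.DataFrame(rows)


# -- file writers (plain-text formats; coordinates 0-based half-open) --------


def write_truth_bed(truth: TruthSet, path: str | Path) -> None:
    df = truth.true_domains[["chrom", "start", "end", "name", "effect"]]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_expression(
    matrix: pd.DataFrame, groups: pd.Series, path: str | Path, groups_path: str | Path
) -> None:
    matrix.to_csv(path)
    groups.rename_axis("sample").to_csv(groups_path)


def read_expression(path: str | Path, groups_path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    matrix = pd.read_csv(path, index_col=0)
    groups = pd.read_csv(groups_path, index_col=0)["group"]
    return matrix, groups


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))
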