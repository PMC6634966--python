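"""Two-channel tiling-array processing.

Probe intensities from a methyltransferase-fusion channel and a
methylase-only control channel are turned into per-probe log2 ratios
(M = log2(fusion/control)), corrected for intensity-dependent dye bias by
LOESS regression of M on mean log intensity (A), and combined across
biological replicates with dye-swap orientation correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

PROBE_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "probe_id",
    "intensity_fusion",
    "intensity_control",
]
GRID_COLUMNS = ["chrom", "start", "end", "probe_id"]


@dataclass(frozen=True)
class NormalizationParams:
    """LOESS (MA) normalization settings.

    loess_span is the fraction of probes in each local fit (the published
    pipeline states LOESS was used but not its span; 0.3 is standard
    MA-normalization practice). pseudocount guards zero intensities.
    robust_iterations applies bisquare reweighting so a minority of truly
    enriched probes does not bias the intensity trend. delta_frac trades
    exactness for speed by linear interpolation between fit points.
    """

    loess_span: float = 0.3
    pseudocount: float = 1.0
    robust_iterations: int = 3
    delta_frac: float = 0.01
    min_a_range: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class ArraySample:
    """One hybridization: ordered probes with raw channel intensities."""

    sample_id: str
    dye_swapped: bool
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes.reset_index(drop=True)
        missing = [c for c in PROBE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        for col in ("intensity_fusion", "intensity_control"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in {col}")
            if (vals < 0).any():
                bad = df.loc[vals < 0, "probe_id"].iloc[0]
                raise ValueError(f"negative intensity at probe {bad}")
        _validate_grid(df)
        self.probes = df


def _validate_grid(df: pd.DataFrame) -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts >= ends).any():
            i = int(np.nonzero(starts >= ends)[0][0])
            raise ValueError(f"probe with start >= end: {grp['probe_id'].iloc[i]}")
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                "probes out of order or overlapping on "
                f"{chrom}: {grp['probe_id'].iloc[i]} then {grp['probe_id'].iloc[i + 1]}"
            )


@dataclass
class ProbeTrack:
    """Ordered per-chromosome probes carrying log2-ratio statistics.

    Columns beyond the grid: M (raw log2 ratio, dye-swap corrected),
    A (mean log2 intensity), M_norm (LOESS-normalized ratio) and, after
    replicate combination, se and n_replicates.
    """

    probes: pd.DataFrame
    sample_id: str = "track"

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)

    def grid(self) -> pd.DataFrame:
        return self.probes[GRID_COLUMNS]

    def signal(self) -> np.ndarray:
        col = "M_norm" if "M_norm" in self.probes.columns else "M"
        return self.probes[col].to_numpy(dtype=float)


def read_probe_table(
    path: str | Path, sample_id: str | None = None, dye_swapped: bool = False
) -> ArraySample:
    """Read and validate a TSV probe table written by the synthetic module
    (chrom, start, end, probe_id, intensity_fusion, intensity_control)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    sid = sample_id if sample_id is not None else Path(path).stem
    return ArraySample(sample_id=sid, dye_swapped=dye_swapped, probes=df)


def write_probe_table(sample: ArraySample, path: str | Path) -> None:
    sample.probes[PROBE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def compute_log_ratio(sample: ArraySample, params: NormalizationParams | None = None) -> ProbeTrack:
    """Form M/A statistics from raw channels, negating M for dye-swapped
    samples so every replicate shares the fusion-over-control orientation.

    Probes where both channels (plus pseudocount) are zero get missing M,
    and are excluded from all downstream statistics.
    """
    params = params or NormalizationParams()
    df = sample.probes.copy()
    f = df["intensity_fusion"].to_numpy(dtype=float) + params.pseudocount
    c = df["intensity_control"].to_numpy(dtype=float) + params.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(f) - np.log2(c)
        a = 0.5 * (np.log2(f) + np.log2(c))
    bad = (f <= 0) | (c <= 0)
    m[bad] = np.nan
    a[bad] = np.nan
    if sample.dye_swapped:
        m = -m
    df["M"] = m
    df["A"] = a
    return ProbeTrack(probes=df, sample_id=sample.sample_id)


def loess_normalize(track: ProbeTrack, params: NormalizationParams | None = None) -> ProbeTrack:
    """Remove the intensity-dependent component of M by local regression on A.

    M' = M - fhat(A), with fhat a tricube-weighted local linear fit of span
    ``loess_span``.  When the dynamic range of A is below ``min_a_range``
    (including the all-identical case) there is no intensity trend to fit
    and the global median of M is subtracted instead, with a warning.
    """
    params = params or NormalizationParams()
    df = track.probes.copy()
    m = df["M"].to_numpy(dtype=float)
    a = df["A"].to_numpy(dtype=float)
    ok = np.isfinite(m) & np.isfinite(a)
    if ok.sum() < 10:
        raise ValueError("need at least 10 probes with defined log2 ratios")
    fitted = np.full(m.shape, np.nan)
    span_a = np.ptp(a[ok])
    if span_a < max(1e-12, params.min_a_range):
        warnings.warn(
            "A range too small to support an intensity trend; "
            "subtracting global median of M instead of a LOESS fit",
            stacklevel=2,
        )
        fitted[ok] = np.median(m[ok])
    else:
        delta = params.delta_frac * span_a
        base = lowess(
            m[ok], a[ok], frac=params.loess_span, it=0, delta=delta, return_sorted=False
        )
        resid_mad = np.median(np.abs(m[ok] - base))
        if params.robust_iterations > 0 and resid_mad > 1e-10:
            base = lowess(
                m[ok],
                a[ok],
                frac=params.loess_span,
                it=params.robust_iterations,
                delta=delta,
                return_sorted=False,
            )
        fitted[ok] = base
    df["M_norm"] = m - fitted
    return ProbeTrack(probes=df, sample_id=track.sample_id)


def combine_replicates(tracks: list[ProbeTrack]) -> ProbeTrack:
    """Per-probe mean and standard error of M' across replicates.

    All tracks must share an identical probe grid.  Probes missing in some
    replicates are averaged over the available ones; a single contributing
    replicate gives SE = 0 by convention.
    """
    if not tracks:
        raise ValueError("no tracks to combine")
    ref = tracks[0].grid()
    for t in tracks[1:]:
        g = t.grid()
        if len(g) != len(ref) or not g.equals(ref):
            if len(g) != len(ref):
                raise ValueError(
                    f"replicate {t.sample_id} has {len(g)} probes, expected {len(ref)}"
                )
            neq = ~(g == ref).all(axis=1)
            probe = ref.loc[neq.idxmax(), "probe_id"]
            raise ValueError(f"replicate {t.sample_id} grid mismatch at probe {probe}")
    mat = np.vstack([t.probes["M_norm"].to_numpy(dtype=float) for t in tracks])
    n = np.isfinite(mat).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    se[n == 0] = np.nan
    df = ref.copy()
    df["M_norm"] = mean
    df["se"] = se
    df["n_replicates"] = n
    return ProbeTrack(probes=df, sample_id="combined")


def write_bedgraph(track: ProbeTrack, path: str | Path, column: str = "M_norm") -> None:
    df = track.probes
    out = df[["chrom", "start", "end", column]].dropna(subset=[column])
    out.to_csv(path, sep="\t", header=False, index=False)


def write_track_tsv(track: ProbeTrack, path: str | Path) -> None:
    track.probes.to_csv(path, sep="\t", index=False)
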