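"""Meta-profiles (end analyses) and chromatin-state signal summaries.

A meta-profile aligns a set of regions at a common anchor (center, start or
end; strand-aware for genes) and averages the normalized probe signal as a
function of distance from the anchor, in fixed-width bins.  The state
summary averages the signal over each labeled region and reports the
per-label distribution, the analysis used to compare binding across
chromatin states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays import ProbeTrack
from .intervals import IntervalSet


@dataclass(frozen=True)
class ProfileParams:
    """align: anchor choice; flank: half-width of the profiled window (bp);
    bin: bin width (bp, flank must be a multiple); weight: 'probe' averages
    over all probe-region incidences, 'region' first averages within each
    region then across regions (the published description is ambiguous
    between the two, so both are exposed)."""

    align: str = "center"
    flank: int = 6000
    bin: int = 300
    weight: str = "probe"

    def __post_init__(self) -> None:
        if self.align not in ("center", "start", "end"):
            raise ValueError("align must be center, start or end")
        if self.flank <= 0 or self.bin <= 0:
            raise ValueError("flank and bin must be > 0")
        if self.flank % self.bin:
            raise ValueError("flank must be a multiple of bin")
        if self.weight not in ("probe", "region"):
            raise ValueError("weight must be 'probe' or 'region'")


def _anchors(regions: pd.DataFrame, align: str) -> tuple[np.ndarray, np.ndarray]:
    """Anchor coordinate and orientation sign (+1/-1) per region."""
    start = regions["start"].to_numpy()
    end = regions["end"].to_numpy()
    strand = (
        regions["strand"].to_numpy()
        if "strand" in regions.columns
        else np.full(len(regions), "+")
    )
    minus = strand == "-"
    if align == "center":
        anchor = (start + end) // 2
        sign = np.ones(len(regions), dtype=int)
    elif align == "start":
        anchor = np.where(minus, end, start)
        sign = np.where(minus, -1, 1)
    else:
        anchor = np.where(minus, start, end)
        sign = np.where(minus, -1, 1)
    return anchor.astype(np.int64), sign


def end_profile(
    track: ProbeTrack, regions: IntervalSet, params: ProfileParams | None = None
) -> pd.DataFrame:
    """Mean signal +/- SE per distance bin across aligned regions.

    Each probe contributes through the bin of its center's (signed) distance
    from the region anchor; distances in [-flank, flank) are kept.  Returns
    a frame with bin_center, mean, se, n per bin.
    """
    params = params or ProfileParams()
    if len(regions) == 0:
        raise ValueError("no regions to profile")
    probes = track.probes
    signal = track.signal()
    centers = ((probes["start"] + probes["end"]) // 2).to_numpy()
    chrom_index = {
        c: np.asarray(g.index) for c, g in probes.groupby("chrom", sort=False)
    }
    n_bins = 2 * params.flank // params.bin
    sums = np.zeros(n_bins)
    sqs = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    region_bins: list[np.ndarray] = []  # per-region bin means for weight='region'
    region_ids: list[np.ndarray] = []
    anchor, sign = _anchors(regions.records, params.align)
    for r, (_, reg) in enumerate(regions.records.iterrows()):
        idx = chrom_index.get(reg["chrom"])
        if idx is None:
            continue
        c = centers[idx]
        lo = np.searchsorted(c, anchor[r] - params.flank, side="left")
        hi = np.searchsorted(c, anchor[r] + params.flank, side="right")
        sel = idx[lo:hi]
        if sel.size == 0:
            continue
        d = (centers[sel] - anchor[r]) * sign[r]
        vals = signal[sel]
        ok = np.isfinite(vals) & (d >= -params.flank) & (d < params.flank)
        if not ok.any():
            continue
        bins = ((d[ok] + params.flank) // params.bin).astype(int)
        v = vals[ok]
        np.add.at(sums, bins, v)
        np.add.at(sqs, bins, v * v)
        np.add.at(counts, bins, 1)
        region_bins.append(v)
        region_ids.append(bins)
    if counts.sum() == 0:
        warnings.warn("no probes within flank of any region; empty profile", stacklevel=2)
    bin_center = -params.flank + params.bin * (np.arange(n_bins) + 0.5)
    if params.weight == "probe":
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            var = np.where(
                counts > 1,
                (sqs - counts * mean**2) / np.maximum(counts - 1, 1),
                np.nan,
            )
            se = np.where(counts > 1, np.sqrt(np.maximum(var, 0) / np.maximum(counts, 1)), 0.0)
            se = np.where(counts == 0, np.nan, se)
        n_out = counts
    else:
        per_region = np.full((len(region_bins), n_bins), np.nan)
        for i, (v, b) in enumerate(zip(region_bins, region_ids)):
            s = np.zeros(n_bins)
            c = np.zeros(n_bins, dtype=int)
            np.add.at(s, b, v)
            np.add.at(c, b, 1)
            per_region[i, c > 0] = s[c > 0] / c[c > 0]
        n_reg = np.isfinite(per_region).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(per_region, axis=0) if len(region_bins) else np.full(n_bins, np.nan)
            sd = np.nanstd(per_region, axis=0, ddof=1) if len(region_bins) else mean
        se = np.where(n_reg > 1, sd / np.sqrt(np.maximum(n_reg, 1)), 0.0)
        se = np.where(n_reg == 0, np.nan, se)
        n_out = n_reg
    return pd.DataFrame({"bin_center": bin_center, "mean": mean, "se": se, "n": n_out})


def state_signal_summary(
    track: ProbeTrack, states: IntervalSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean signal per labeled region, grouped by state label.

    ``states`` records need a label column (``name`` holds the region id;
    the label is taken from a ``state`` column, falling back to ``name``).
    Regions containing no probes are excluded and counted.  Returns
    (per-region table, per-state summary with quantiles).
    """
    states.assert_disjoint()
    probes = track.probes
    signal = track.signal()
    centers = ((probes["start"] + probes["end"]) // 2).to_numpy()
    chrom_index = {c: np.asarray(g.index) for c, g in probes.groupby("chrom", sort=False)}
    label_col = "state" if "state" in states.records.columns else "name"
    rows = []
    n_empty = 0
    for _, reg in states.records.iterrows():
        idx = chrom_index.get(reg["chrom"])
        if idx is None:
            n_empty += 1
            continue
        c = centers[idx]
        lo = np.searchsorted(c, reg["start"], side="left")
        hi = np.searchsorted(c, reg["end"], side="left")
        vals = signal[idx[lo:hi]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            n_empty += 1
            continue
        rows.append(
            {
                "region": reg["name"],
                "state": reg[label_col],
                "mean_signal": float(vals.mean()),
                "n_probes": int(vals.size),
            }
        )
    per_region = pd.DataFrame(rows, columns=["region", "state", "mean_signal", "n_probes"])
    if len(per_region):
        summary = (
            per_region.groupby("state")["mean_signal"]
            .agg(
                n_regions="size",
                mean="mean",
                q25=lambda s: s.quantile(0.25),
                median="median",
                q75=lambda s: s.quantile(0.75),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["state", "n_regions", "mean", "q25", "median", "q75"])
    summary.attrs["n_excluded_regions"] = n_empty
    per_region.attrs["n_excluded_regions"] = n_empty
    return per_region, summary


def plot_profile(profile: pd.DataFrame, path) -> None:
    """Optional matplotlib export of a meta-profile with an SE band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile["bin_center"], profile["mean"], color="tab:blue")
    ax.fill_between(
        profile["bin_center"],
        profile["mean"] - profile["se"],
        profile["mean"] + profile["se"],
        alpha=0.3,
        color="tab:blue",
        linewidth=0,
    )
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
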