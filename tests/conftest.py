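"""Shared fixtures: small synthetic configurations and the array pipeline
helper (simulate -> log ratio -> LOESS -> combine -> call)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import damidpipe as dp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def array_pipeline(cfg: dp.SyntheticConfig):
    """Full array path on a synthetic configuration; returns
    (grid, truth, combined track, called domains, diagnostics)."""
    grid = dp.make_probe_grid(cfg)
    truth = dp.plant_domains(cfg, grid)
    samples = dp.simulate_damid_arrays(cfg, grid, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracks = [dp.loess_normalize(dp.compute_log_ratio(s)) for s in samples]
    combined = dp.combine_replicates(tracks)
    domains, diagnostics = dp.call_domains(combined)
    return grid, truth, combined, domains, diagnostics


def truth_interval_set(truth: dp.TruthSet) -> dp.IntervalSet:
    df = truth.true_domains[["chrom", "start", "end", "name", "effect"]].rename(
        columns={"effect": "score"}
    )
    return dp.IntervalSet(df, kind="domain")


def make_track(values, spacing: int = 100, chrom: str = "chr1") -> dp.ProbeTrack:
    """A ProbeTrack with given normalized signal on an even grid."""
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * spacing
    return dp.ProbeTrack(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + spacing // 2,
                "probe_id": [f"p{i:05d}" for i in range(len(values))],
                "M_norm": values,
            }
        ),
        "test",
    )


@pytest.fixture(scope="session")
def small_cfg() -> dp.SyntheticConfig:
    """Small but fully-featured study: one 6 Mb chromosome, 20 domains."""
    return dp.SyntheticConfig(
        seed=7, n_chromosomes=1, chromosome_length=6_000_000, n_domains=20, n_peaks=5,
        n_genes=300, n_indirect_de=24,
    )


@pytest.fixture(scope="session")
def noise_free_cfg() -> dp.SyntheticConfig:
    """Noise-free limit: zero noise, no dye bias, flat abundance."""
    return dp.SyntheticConfig(
        seed=3, n_chromosomes=1, chromosome_length=6_000_000, n_domains=20, n_peaks=5,
        noise_sd=0.0, intensity_bias_amplitude=0.0, abundance_sd=0.0,
        n_genes=300, n_indirect_de=24,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    return array_pipeline(small_cfg)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_cfg):
    return array_pipeline(noise_free_cfg)
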