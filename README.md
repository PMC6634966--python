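# damidpipe

Analysis pipeline for two-channel DamID tiling-array chromatin profiling,
with a synthetic-data benchmark carrying planted ground truth.

DamID maps where a chromatin protein binds the genome: a Dam
methyltransferase fused to the protein of interest methylates GATC sites
near its binding sites, and methylated fragments are hybridized against a
methylase-only control on a tiling array (~300 bp probe spacing). The
working statistic per probe is the log2 ratio

    M = log2(fusion / control),    A = ½ · log2(fusion · control)

`damidpipe` implements the computational path from raw probe intensities to
biological summaries:

- **Normalization** — LOESS regression of M on A removes intensity-dependent
  dye bias (`M′ = M − f̂(A)`); dye-swap technical replicates are sign-corrected
  and replicates combined per probe (mean ± SE).
- **Domain calling** — a sliding edge filter (window 199 probes) scores each
  probe `e_i = mean(M′_{i+1..i+h}) − mean(M′_{i−h..i−1})`; transitions with
  `|e| > 0.3` survive sign-aware non-maximum suppression, are paired
  up→down, boundary-refined by a mean-shift changepoint fit, and kept as
  domains when ≥ 70% of enclosed probes have `M′ > 0`. A quantile-based
  single-peak caller complements the broad-domain caller.
- **Domain-set comparison** — the minimum-overlap rule (a pair matches when
  at least one domain is ≥ 80% covered by the intersection), plus
  strand-aware domain→gene assignment (gene body + 2 kb promoter window).
- **Differential expression** — empirical-Bayes moderated t-test with a
  method-of-moments prior `(d₀, s₀²)` on log variances,
  `s̃² = (d₀s₀² + d s²)/(d₀ + d)`, Benjamini–Hochberg FDR, and the
  p < 0.05 ∧ ≥ 2-fold filter.
- **Integration** — hypergeometric overlap of bound and regulated gene
  sets, putative direct targets (bound DEGs), and the fraction of
  bound-and-regulated genes activated vs repressed by the factor.
- **Meta-profiles** — signal averaged around aligned region anchors
  (center/start/end, strand-aware), and per-chromatin-state signal
  summaries.
- **Motif enrichment** — IUPAC scanning for the E-box CANNTG (palindromic,
  so forward counting is complete) against generated random background,
  with a label-permutation p-value.
- **Phenotype statistics** — percent→count reconstruction under explicit
  rounding assumptions, Fisher's exact test (two-sided point-probability
  rule), G-TRACE lineage-tracing class fractions, and life-table survival
  summaries (fraction surviving past a horizon, DT50).

The synthetic module generates every input with known truth — probe grids,
planted domains and single peaks on the log2-ratio track, replicate
structure including a dye swap, a gene annotation with a configurable
fraction of domains linked to genes, expression matrices with planted
2-fold effects, random sequences, and phenotype tables — so every stage is
testable against what was planted.

## Worked example

```python
import damidpipe as dp

cfg = dp.SyntheticConfig(seed=1)                       # 2 x 10 Mb, 50 domains
grid = dp.make_probe_grid(cfg)
truth = dp.plant_domains(cfg, grid)
samples = dp.simulate_damid_arrays(cfg, grid, truth)   # 2 replicates + dye swap

tracks = [dp.loess_normalize(dp.compute_log_ratio(s)) for s in samples]
combined = dp.combine_replicates(tracks)
domains, diagnostics = dp.call_domains(combined)

truth_set = dp.IntervalSet(
    truth.true_domains.rename(columns={"effect": "score"}), kind="domain"
)
metrics = dp.recovery_metrics(domains, truth_set, cfg.probe_spacing)
print(f"called {len(domains)} domains from {diagnostics['n_up']} up- and "
      f"{diagnostics['n_down']} down-transitions")
print(f"recovery F1 = {metrics['f1']:.3f}, "
      f"mean boundary error = {metrics['mean_boundary_error_probes']:.2f} probes")
```

prints

```
called 50 domains from 50 up- and 50 down-transitions
recovery F1 = 1.000, mean boundary error = 0.17 probes
```

i.e. at the default study conditions (domain effect 1.0 log2 units against
noise SD 0.25 per replicate, three replicates), the caller recovers every
planted domain with sub-probe boundary accuracy.

## Command line

The same stages are available as a CLI over a single YAML configuration:

```sh
damidpipe validate --config config.yaml
damidpipe run-all --seed 1 --outdir out/          # full pipeline + report.json
damidpipe simulate --seed 1 --outdir out/         # or stage by stage
damidpipe normalize --seed 1 --outdir out/
damidpipe call-domains --seed 1 --outdir out/ --edge-threshold 0.3
```

Each stage reads the files earlier stages wrote under `--outdir`, so a
stage-by-stage run reproduces `run-all` byte for byte at the same seed.

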