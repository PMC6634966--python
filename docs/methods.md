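# Methods

This note documents the models, parameter choices, and numerical decisions
behind `damidpipe`, and what the synthetic benchmark does and does not
establish about real data.

## Signal model and normalization

A two-channel tiling array measures, per probe, a fusion-channel intensity
(Dam fused to the protein of interest) and a control-channel intensity
(unfused methylase, controlling for non-specific accessibility). The
per-probe statistics are `M = log2((fusion + c)/(control + c))` and
`A = ½·log2((fusion + c)(control + c))` with pseudocount `c = 1` intensity
unit guarding zeros. Probes with a zero in both channels (at `c = 0`) are
flagged missing and excluded, never imputed.

Dye-swapped technical replicates have their physical channels exchanged;
`compute_log_ratio` negates M for them so all replicates share the
fusion-over-control orientation **before** normalization, which assumes a
common orientation.

LOESS normalization removes the intensity-dependent component:
`M′ = M − f̂(A)`, where f̂ is a tricube-weighted local **linear** fit with
span 0.3 (fraction of probes per local fit). The span is a design choice —
the underlying study states only that LOESS was used — and is configurable.
Three implementation details matter:

- **Robustness.** Truly enriched probes are a ~10% minority that sits
  systematically above the bulk; a non-robust fit would absorb part of the
  biological signal into the "trend". Three bisquare reweighting
  iterations reduce the residual bias of out-of-domain probes to ≲0.03
  log2 units per A-decile at the default conditions. A first non-robust
  pass detects exactly-noise-free input (zero residual MAD) and skips
  reweighting there, avoiding a 0/0 in the robust weights.
- **Degenerate A.** When the dynamic range of A is below `min_a_range`
  (0.1 log2 units) there is no intensity trend to identify, and the global
  median of M is subtracted instead (with a warning). The threshold is not
  merely cosmetic: with a constant baseline intensity the pseudocount
  induces a tiny spurious A–M dependence through which LOESS would regress
  out the planted effect itself.
- **Speed.** The fit uses linear interpolation between evaluation points
  spaced 1% of the A-range (`delta_frac`), standard LOWESS practice at
  array scale.

Normalization is *not* idempotent to machine precision on enriched data:
each reapplication re-fits the enriched minority and moves the track by up
to a few hundredths of a log2 unit. It is idempotent (≤1e-6) exactly where
local-linear regression is unbiased — a linear M–A trend without
enrichment — and the tests assert both the exact and the practical bound.

Replicates are combined per probe as the mean of M′ over non-missing
replicates with the standard error `sd/√n` (SE = 0 by convention for a
single contributing replicate).

## Domain calling

Sharp transitions are located with a sliding edge filter of
`window_probes = 199` (an odd count; half-window h = 99): the score at
probe i is the difference between the mean M′ of the next h probes and the
mean of the previous h, center excluded. Scores are undefined within h
probes of a chromosome end rather than computed on truncated windows,
avoiding edge-bias artifacts.

Transitions are probes with `|e| > edge_threshold` (0.3 log2 units, the
published operating point) that are also the maximum among **same-sign**
scores within one window; exact ties resolve to the leftmost probe. The
suppression is sign-aware because the up- and down-edge of a domain
shorter than one window lie within one window of each other and would
otherwise suppress one another.

Each up transition opens a candidate that the next down transition closes
(enclosed probes: strictly after the up index through the down index).
A trailing up transition closes at the chromosome end and a leading down
opens at the start (configurable, counted in diagnostics); consecutive
same-sign transitions are counted and skipped.

**Boundary refinement.** For a domain of L probes with L < window, the
edge-score plateau puts the transition up to (window − L) probes outside
the true boundary. Each candidate is therefore refined with a mean-shift
changepoint fit: with μ estimated from the upper half of the candidate's
signal, the start is the index maximizing the tail sum of (M′ − μ/2) and
the end the index maximizing the head sum — the maximum-likelihood split
of a background(0)/domain(μ) model with equal variances. The refinement is
exact on noise-free steps, leaves well-placed boundaries untouched, and
brings the mean boundary error from ~4 probes (naive flank trimming) to
~0.2 probes at the default noise level.

A refined candidate becomes a domain when it encloses at least
`min_probes_per_domain = 3` probes (suppressing single-probe calls) of
which at least `min_positive_fraction = 0.70` have strictly positive M′ —
the published positive-probe rule.

The single-peak caller is an extension with no published counterpart:
maximal runs of ≥ 2 consecutive probes with M′ strictly above the
per-chromosome 0.95 quantile, excluding runs inside called domains. On a
constant track the quantile equals every value and no peak is called.

## Domain-set comparison and gene assignment

Two domain sets are compared under the minimum-overlap rule: a pair
matches when the intersection covers at least `min_fraction = 0.80` of at
least one member (`mode="either"`, following the published "at least one
domain had to have at least 80% overlap with the other"); `reciprocal`
requires both. Matching is one-to-one, greedy by largest overlap, ties to
the leftmost pair. Recovery benchmarking uses 50% reciprocal overlap as
the match criterion plus the mean absolute boundary offset in probes.

Gene assignment is a design choice (the original region→gene rule is
unpublished): a gene is bound when any domain overlaps (≥1 bp) its body or
the strand-aware 2 kb window upstream of its transcription start
(downstream window 0 by default). All windows are configurable; every
downstream fraction inherits this mapping choice.

## Moderated t-test and the DE filter

For a two-group comparison with n₁, n₂ replicates (d = n₁+n₂−2 residual
df), per-gene pooled variances s² are shrunk toward a prior:
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)`, and
`t = (mean_kd − mean_ctl)/√(s̃²(1/n₁+1/n₂))` is referred to a t
distribution on d₀ + d df. With d₀ = 0 this is the ordinary pooled t
(verified against the closed form); with d₀ → ∞ every variance equals s₀².

The prior is estimated by method of moments on z = log s²: under
s² ~ s₀²·F(d, d₀), `var(z) = ψ′(d/2) + ψ′(d₀/2)` and
`E[z] = log s₀² + ψ(d/2) − ψ(d₀/2) + log(d₀/d)`; ψ′ is inverted by Newton
iteration. When var(z) does not exceed ψ′(d/2), d₀ = ∞ (the homoscedastic
case — which is also the truth for the synthetic generator, and the
estimator recovers it). Genes with zero variance are excluded from the
moment estimation and handled through the moderated variance. The
implementation agrees with Bioconductor limma's eBayes to |Δp| < 0.01 on
heteroscedastic test data (limma is used only as an oracle, never called
by the pipeline).

Tests are two-sided. The published filter — p < 0.05 and ≥ 2-fold change —
is applied to raw p by default with BH q reported alongside; whether the
original "(p<0.05)" referred to raw or adjusted p is ambiguous, so
`filter_on="q"` switches the significance arm to the q-value.

BH q-values follow the step-up definition
`q_i = min_{j ≥ rank(i)} m·p_(j)/j`, clipped at 1, input order preserved.

## Integration

The hypergeometric overlap test is upper-tail (enrichment), summed in log
space from k to min(nA, nB). The gene universe is the annotation the
analysis ran on — never the genome — and every report states it, because
overlap p-values are meaningless without the universe. The
direction-of-regulation summary reports, over bound-and-regulated genes,
the fraction down upon knockdown (factor-activated) vs up
(factor-repressed). Putative direct targets are the bound DEGs with the
exact bound fraction of the DEG list.

## Meta-profiles and state summaries

Probes contribute to the bin of their center's signed distance from the
region anchor (center, or strand-aware start/end); distances in
[−flank, flank) with bin = 300 bp (the probe spacing) and flank = 6000 bp
by default (flank must be a multiple of bin). Per-bin SE is computed
across probe contributions by default; `weight="region"` first averages
within regions and then across them — the published description is
ambiguous between the two, so both are exposed. State summaries average M′
over each labeled region and report per-label quantiles; probe-free
regions are excluded and counted.

## Motif enrichment

IUPAC patterns compile to overlapping-match regular expressions; the
default CANNTG E-box is reverse-complement symmetric so forward-only
counting is complete (the dedup mode verifies this). An N in a *sequence*
matches nothing. Enrichment is the foreground/background per-kb density
ratio; significance is an empirical label-permutation p,
`(1 + #{ratio* ≥ ratio}) / (n_perm + 1)`, never below 1/(n_perm+1). The
published motif E-value came from an external tool whose background model
is not reproducible and is not a target. Analytically, a degenerate
pattern with four fixed positions has background density 4⁻⁴ per position
(≈3.9/kb at GC 0.5); planting r exact instances per kb predicts enrichment
≈ 1 + r/3.9, which the tests assert.

## Phenotype statistics

Published imaging/organismal comparisons report percentages with n.
`counts_from_percent` reconstructs integer counts either as
round(p·n/100) or as *every* count whose percentage rounds back to the
printed value (at the printed precision), so significance claims can be
checked under each consistent reading. The exact conditional test is
Fisher's, with the two-sided point-probability rule (all margin-fixed
tables whose probability does not exceed the observed one, with a 1e-7
relative tie tolerance); chosen because the counts are small and the
original analysis names no test. Survival uses a simple life table over
whole days — censored individuals count as alive through their censor day
and leave the denominator after — reporting the fraction surviving past a
horizon and DT50, the first day cumulative deaths reach half the starting
cohort. No Kaplan–Meier/log-rank machinery is included.

## The synthetic benchmark: what it emulates, and what it does not

The generator emulates a NimbleGen-style design: fixed ~300 bp probe
spacing, two biological replicates plus one dye-swap technical replicate,
and a log2-ratio track with planted broad domains (default: 50 domains of
15–60 kb, effect 1.0 log2 units) and single peaks (20 spikes of 1–3
probes, effect 2.0). Channel intensities are derived from a per-probe
abundance `A ~ N(10, 1)` log2 units with the effect split symmetrically
(`fusion = 2^(A+M/2)`, `control = 2^(A−M/2)`), so A is independent of
domain membership and the planted effect is orthogonal to the
LOESS-removable dye bias (amplitude 0.5·tanh(A−10) by default, applied in
the physical dye orientation). Per-replicate Gaussian noise (SD 0.25) acts
on M directly.

Two placement constraints make recovery well-posed and are deliberate
study conditions, not conveniences to be tuned per test: domains keep
≥110 probes from chromosome ends (edge scores are undefined within a
half-window of an end) and ≥210 probes from each other (two same-sign
transitions within one 199-probe window would suppress each other). The
default genome is 2 × 10 Mb (~66,666 probes), putting ~10% of probes in
domains — a realistic coverage for a transcription-factor binding map and
the regime where robust LOESS debiasing holds; at several-fold denser
coverage the trend fit is visibly biased by the enriched minority.

Expression matrices are log-scale, 3 control vs 3 knockdown replicates,
i.i.d. Gaussian noise (SD 0.25), gene baselines N(8, 1.5). Of 50 domains,
80% are linked to a gene placed inside the domain; linked genes are DE
with |log2FC| = 1 (2-fold), 70% of them factor-activated (down upon
knockdown). 80 additional unlinked DE genes are placed ≥3 kb from any
domain, giving a planted direct-target fraction of 1/3 among DEGs.
Survival cohorts for the life-table demonstration are truncated-normal
death days (control mean day 45, targeted mean day 23), matching the
reported design scale of n = 150 per group.

What passing tests show: the caller, normalizer, and statistics recover
exactly what was planted, at the stated operating point, under Gaussian
noise and a smooth monotone dye bias. What they do not show: robustness to
spatial on-slide artifacts, sequence-composition probe biases,
heavy-tailed or correlated probe noise, partially methylated boundaries,
or mapping/annotation errors — none of which the generator emulates.
Headline genomic counts of the original study (thousands of binding
regions, specific DEG counts) derive from the deposited array data and are
not reproduction targets at this scale.

## Numerical conventions and degenerate inputs

All genomic coordinates are 0-based half-open; adjacent intervals overlap
by 0 bp. Probe order is preserved through every transform; no operation
adds, drops, or reorders probes (missing values are flagged, not removed).
Quantiles use numpy's default linear interpolation. Argmax ties resolve to
the leftmost index throughout (transition NMS, changepoint refinement,
DT50). Empty inputs raise (`plant_domains` on an empty grid, Fisher on an
all-zero table, G-TRACE with no polyploid cells) or return typed empties
(zero planted domains, zero transitions, zero-record FASTA). Every
generator and every pipeline stage is deterministic under a fixed seed;
per-stage seeds derive from the global seed by CRC32 of the stage name, so
stages can be re-run in isolation and reproduce the full run's outputs.
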