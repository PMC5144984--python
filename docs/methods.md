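# Methods

This note documents the statistical model behind `neighborcorr`, the design
choices where the method was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Neighbor pairing and distance

Genes are restricted to protein-coding biotypes, grouped by chromosome and
sorted by strand-aware TSS (the annotated 5′ terminus: `start` on `+`,
`end` on `−`). Sorting is stable on `(tss, gene_id)` so pairing is
deterministic under coordinate ties. "*k* nearest neighbors" is implemented
as rank separation ≤ *k* in this sorted order rather than *k*-nearest by bp:
it is deterministic under ties and yields the expected ≈ *k*·*n* pairs per
genome (exactly Σᵢ min(i, k) per chromosome — 594,950 for a 6,000-gene
chromosome at *k* = 100, i.e. "around 600,000" at yeast scale). Each
unordered pair is stored once with the upstream-by-TSS gene first, which
also fixes the orientation classes: `(−,+)` divergent, `(+,−)` convergent,
same strand parallel.

Intergenic distance is |TSS_b − TSS_a|: 5′-start to 5′-start, not the gap
between gene bodies. Annotation sources often lack UTR sub-features, so the
gene record's 5′ terminus stands in for the 5′ UTR start.

Pairs whose two members share an operon are removed (co-transcription would
trivially inflate correlation); genes in *different* operons are kept.
Duplicated-gene pairs are flagged, with removal a caller option, since
duplicate-driven coexpression is a separate question from distance decay.
Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on load.

## Correlation

Detection filter: a gene must have a value > 0 (and non-missing) in at least
80% of experiments; TPM zero is taken as the natural undetected state.
Values are ranked within each experiment (average ranks for ties — the
standard, deterministic convention), and the correlation of a pair is the
Pearson correlation of the two rank trajectories over experiments where both
genes were assayed, with a floor of `min_obs = 10` joint observations.
Missing values (unassayed, distinct from zero) propagate as NaN and are
handled pairwise-complete.

Two properties of this statistic are worth noting, because they shaped both
the generator and the tests:

1. **It is not per-gene-profile Spearman.** Ranking across genes within an
   experiment then correlating across experiments differs from ranking each
   gene's own profile. The ranked-Pearson ≡ Spearman identity holds exactly
   when the ranking axis is the correlation axis, and that is how the
   oracle-equivalence test is framed (`spearman(x, y)` vs an independent
   implementation).
2. **An equal-loading genome-wide factor is invisible to it.** Within-sample
   ranks are a permutation of 1..m, so a factor that shifts every gene
   equally cancels, and the *average* pairwise rank correlation in any
   dataset is exactly −1/(m−1). Consequences: the cross-chromosome
   background median sits slightly below zero (visible in the worked
   example), and a distance-independent correlation plateau can only be
   produced by structure that moves a *subset* of genes jointly.

Background null: each gene is paired with 20 genes sampled without
replacement (per source gene) from other chromosomes; the summary is the
median with a percentile (2.5/97.5) bootstrap 95% CI over 10,000 resamples.
Percentile rather than BCa because only a simple median interval is needed;
all RNG consumption flows from one seeded generator recorded in the output.

## Smoothing and decay fit

Pairs sorted by distance are smoothed with a sliding median of window 1000
pairs, step 1 (maximal smoothness), emitting per-window median distance,
median value, and the 25/75 percentiles for interquartile bands. The
production implementation is pandas' rolling skiplist median, which is
bit-identical to the naive per-window recomputation the tests use as oracle.

The smoothed curve is fitted to ρ(d) = ρ₀·e^(−λd) + c by bounded
trust-region least squares (`scipy.optimize.least_squares`, bounds
ρ₀ ∈ [0, 2], λ > 0, c ∈ [−1, 1]; widened to the percentage scale for the
tissue-overlap statistic), unweighted, tolerances 1e-10, at most 10,000
evaluations. Initialization is derivative-free: c₀ = median of the far
decile, ρ₀₀ = near-decile median − c₀, λ₀ = reciprocal of the distance where
the curve first crosses c₀ + ρ₀₀/e (falling back to the median distance).
The fit runs on the smoothed curve; raw-pair fitting is available as
`fit_raw_pairs` for sensitivity analysis. `dexp = 1/λ`. A fit is flagged
unreliable (`converged = False`) when the optimizer fails, λ collapses to
its floor, or ρ₀ is indistinguishable from zero (flat curve) — `dexp` should
not be interpreted in those cases.

## Tissue overlap

Pair overlap is the Jaccard percentage of the two genes' tissue-term sets;
terms are case-normalized flat strings with no ontology expansion. Genes
without annotation are excluded from pairs (counts logged); no
ubiquitous/maternal-style term exclusion is applied. The overlap records
feed the same smoothing/fitting stack with `statistic_name = "overlap"`.

## Stratified comparisons

Insulator sites arrive as BED replicates; the replicate intersection
(merge → intersect → merge, via pyranges) is used. A pair is "flanked" by a
factor when ≥ 1 intersected site overlaps the open interval between the two
TSSs — the reading that matches insulators acting between neighbors; the
bracketing alternative (sites on both distal sides, none between) is
available as `mode="outside"`. Raw comparisons restrict to pairs closer
than 10 kb (configurable), where group differences are largest. Two distance
controls are provided: a shared absolute window (default 30–40 kb) and
histogram matching (per shared distance bin, every group is downsampled
without replacement to the smallest per-group bin count; the post-matching
two-sample KS statistic between group distance distributions must be
≤ 0.05). Group summaries are medians; rank-sum p-values can be attached for
description only.

## Synthetic data

The generator emulates the statistical structure the pipeline is meant to
detect, not the biology that produces it:

- **Genome**: TSS positions are cumulative log-normal gap draws (defaults
  `gap_log_mean = 8.0`, `gap_log_sd = 1.5`: median gap ≈ 3 kb with a heavy
  right tail — compact-genome-like spacing that still populates windows out
  to hundreds of kb). Defaults: 4 chromosomes × 1000 genes.
- **Expression**: a latent Ornstein–Uhlenbeck (AR(1)) Gaussian process along
  each chromosome — exact for the exponential kernel in 1-D, linear time —
  mixed as √a·z + √c_sim·g_chrom + √(1−a−c_sim)·η, then mapped through an
  exponential link and column-scaled to TPM (strictly increasing, hence
  invisible to ranks). Defaults δ = 10 kb, a = 0.3, c_sim = 0.05, 200
  experiments. The baseline factor `g_chrom` is shared per *chromosome*, not
  genome-wide: as noted above, an equal-loading genome-wide factor cancels
  under within-experiment ranking and would leave no plateau in the Spearman
  statistic, whereas a chromosome-block factor is rank-visible and gives all
  same-chromosome pairs the intended floor.
- **Attenuation budget**: rank correlation of a bivariate normal is
  (6/π)·asin(ρ/2) ≈ 0.955ρ, shrinking amplitudes ≲ 4.7% without moving the
  distance scale. The block-baseline is attenuated further (ranking against
  the ~3/4 of genes outside the block absorbs part of the shift), so a
  generated c_sim = 0.05 is recovered as ≈ 0.033 — the recovery tolerance of
  ±0.03 on c covers this.
- **Tissue maps**: per tissue term, membership is a stationary two-state
  Markov process along the chromosome (inherit with probability
  e^(−gap/δ_z), else re-draw at the stationary rate p = set size / n
  tissues), giving indicator correlation exactly e^(−d/δ_z). Because the
  Jaccard map is convex in that correlation, the overlap curve decays
  somewhat faster than the latent process; δ_z is therefore pre-calibrated
  from the closed-form overlap curve so that the best-fit exponential decays
  at the requested δ_t (default 20 kb).
- **Confounds**: with `orientation_confound`, each gene's strand is drawn
  conditional on the preceding gap (divergent configurations concentrate on
  small gaps, convergent on large); with `insulator_confound`, site
  placement probability grows with gap size. Neither touches the expression
  model, so distance is the only true driver and a correct stratified
  analysis must see group effects vanish under distance control. Two
  jittered replicates per factor exercise the replicate-intersection path.

What the generator does **not** emulate: count noise and library-size
effects (values are noise-free transforms of Gaussians), batch structure,
missing-data patterns of real compendia, operonic co-transcription, gene
families/duplications, chromatin domains with sharp boundaries, and any
direct regulatory effect of orientation or insulators. Passing recovery
tests therefore demonstrates correctness of the *estimator stack* under the
stated decay model, not robustness to every failure mode of real data.

## Problem sizes and determinism

Validation runs use 4 chromosomes × 1000 genes, 200 experiments and k = 100
(≈ 380,000 pairs) for decay recovery — large enough that the sliding-median
window of 1000 spans ≲ 0.3% of pairs — with recovery medians over 20 seeds
(10 in the acceptance script) for δ ∈ {2, 10, 100} kb; the null-coverage
study uses 1500 genes on 3 chromosomes with 20 experiments and 100 replicate
runs, a regime where the exact −1/(n−1) rank-null is negligible against the
CI width. All generators draw from `numpy` Generators seeded per stream from
one configured seed; reruns are byte-identical, and every CLI run records
its resolved config, seed, and input checksums in a manifest.

## Known limitations

- dexp carries no confidence interval; a bootstrap over pairs is a
  documented extension, not implemented.
- Alternative decay laws (power law, bi-exponential) are not fitted, so the
  exponential's adequacy is assumed, not tested.
- TSS selection is gene-level; transcript isoforms with distinct starts are
  not resolved.
- The paper-scale analysis on real compendia requires external downloads and
  is out of scope here; all quantitative guarantees are for the synthetic
  conditions above.
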