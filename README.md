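# neighborcorr

Genome-wide analysis of how the transcriptional correlation of neighboring
genes decays with the distance between them.

Across eukaryotes, genes that sit close together on a chromosome tend to be
correlated in expression, and the strength of that correlation falls off with
the distance between their transcription start sites (TSS). One mechanistic
reading is enhancer sharing: an enhancer influences any compatible promoter
within physical reach, so regulatory input — and hence expression — is shared
over a characteristic genomic length scale. `neighborcorr` implements the
standard computational pipeline for quantifying this effect from a gene
annotation and an expression compendium, for computational biologists who
want a tested, reproducible version of the analysis plus a synthetic-data
harness that validates every stage against known ground truth.

## The model

Every protein-coding gene is paired with its *k* = 100 nearest neighbors on
the same chromosome (rank separation in TSS-sorted order). For each pair the
pipeline computes the intergenic distance *d* (TSS-to-TSS, strand-aware) and
the Spearman correlation ρ of the two genes across experiments — TPM values
are ranked within each experiment and the Pearson correlation of the rank
trajectories is taken, ρ = cov(r₁, r₂)/(σ₁σ₂). Pairs sorted by distance are
smoothed with a sliding median (window 1000 pairs, step 1) and fitted to an
exponential decay

    ρ(d) = ρ₀ · exp(−λ d) + c

whose reciprocal rate

    dexp = 1 / λ

is the characteristic distance over which gene neighbors remain correlated
above the baseline *c*. A null level is estimated by pairing each gene with
20 random genes from *other* chromosomes and bootstrapping the median
(10,000 resamples, percentile 95% CI).

Supporting analyses:

- **Tissue overlap** (`spatial_overlap`): for genes annotated with in
  situ-style tissue terms, the Jaccard percentage
  100·|A∩B|/|A∪B| of a pair's tissue sets is pushed through the same
  smoothing/fitting stack, giving a spatial-coexpression dexp.
- **Distance-controlled strata** (`stratified`): pairs grouped by strand
  orientation (divergent / parallel / convergent) or by whether an insulator
  binding site (ChIP replicate intersection) lies between their TSSs show
  different correlation distributions — but the groups also differ in
  distance. Restricting all groups to a shared distance window (30–40 kb) or
  histogram-matching their distance distributions shows whether any direct
  group effect remains.
- **Synthetic data** (`synthetic_data`): multi-chromosome gene maps with
  log-normal intergenic gaps, expression whose pairwise correlation decays as
  a·exp(−d/δ)+c by construction (an Ornstein–Uhlenbeck latent process along
  each chromosome), tissue maps with a known overlap decay scale, and
  insulator/orientation confounds coupled to gap size with no direct
  expression effect.

## Worked example

```python
from neighborcorr import (SimulationConfig, simulate_genome, simulate_expression,
    neighbor_pairs, detection_filter, rank_by_experiment, pair_correlations,
    background_correlation, sliding_median, fit_exponential_decay)

cfg = SimulationConfig(delta=10_000, amplitude=0.3, shared_baseline=0.05, seed=7)
genes = simulate_genome(cfg)                      # 4 chromosomes x 1000 genes
expr = simulate_expression(genes, cfg)            # 200 synthetic experiments

pairs = neighbor_pairs(genes, k=100)
ranked = rank_by_experiment(detection_filter(expr, min_frac=0.8))
corr = pair_correlations(ranked, pairs, min_obs=10)
curve = sliding_median(corr, window=1000)
fit = fit_exponential_decay(curve)
bg = background_correlation(ranked, genes, n_per_gene=20, n_boot=10_000, seed=7)

print(f"pairs: {len(pairs)}  correlated: {len(corr)}")
print(f"dexp = {fit.dexp:,.0f} bp  (rho0={fit.rho0:.3f}, c={fit.c:.3f})")
print(f"background median rho = {bg.median_rho:.4f} "
      f"[{bg.ci_low:.4f}, {bg.ci_high:.4f}]")
```

Output:

```
pairs: 379800  correlated: 379800
dexp = 10,187 bp  (rho0=0.294, c=0.033)
background median rho = -0.0119 [-0.0126, -0.0112]
```

The fitted dexp of ~10.2 kb recovers the generating correlation length
δ = 10 kb within 2%. The amplitude 0.294 is the generating 0.3 minus the
expected rank-correlation attenuation; the plateau 0.033 reflects the
baseline 0.05 after the same attenuation (see `docs/methods.md`). The
background median is slightly *negative* — within-experiment ranks sum to a
constant, so unlinked pairs sit just below zero — and far below the
neighbor-pair signal.

The same pipeline runs from the shell on real files (GFF3/GTF/TSV
annotation, TSV expression matrix, BED insulator replicates):

```bash
neighborcorr simulate --seed 7 --outdir data/          # or bring your own files
neighborcorr all --config analysis.yaml
```

Each run writes per-stage TSV/JSON outputs, a resolved config, and a
manifest with input checksums so results are reproducible byte for byte.

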