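# Methods

## Simulation model

The generator emulates a two-group bulk RNA-seq experiment (treated vs
vehicle, gene-level counts). For gene g and sample j,

    K_gj ~ NB(mean μ_gj, dispersion φ),  var = μ + φμ²
    μ_gj = s_j · q_g · 2^(β_g · x_j)

where x_j ∈ {0,1} is the treated indicator, q_g the baseline mean, s_j a
library scale factor, and β_g the planted log2 effect. Sampling is a
gamma–Poisson mixture (λ ~ Gamma(1/φ, φμ), K ~ Poisson(λ)), which is the
exact NB and remains stable down to the Poisson limit φ → 0.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2,000 | desk-scale detected-gene set; large enough for BH to bite |
| n_samples_per_group | 3 | the replicate floor typical of animal transcriptomics |
| baseline_mean_log_range | (1, 3) log10 | counts 10–1,000, the informative range at ~25 M reads/sample |
| dispersion φ | 0.1 | a typical bulk biological CV² of 0.1 between replicates |
| focal_gene_factor | 2.64 | the decorin-like planted effect, DOWN in treated |
| de_log2fc_magnitude | 1.5 | strong-but-plausible DE (~2.8-fold), random sign |
| n_de_genes | 150 | exceeds the worst-case planted-term budget (5·⌈0.8·30⌉ = 120) |
| n_terms / term_size_range | 200 / (10, 30) | mid-size biological-process-like terms |
| n_planted_terms / overlap | 5 / 0.8 | planted terms get ≥ 80% of members forced DE |
| s_j range | ±0.2 log2 | library-size spread large enough that normalization matters, small enough to be benign |

One global seed expands into three per-stage child seeds via
`numpy.random.SeedSequence(seed).spawn` (annotation, signal planting,
counts), so every stage — and the whole triple — is bit-reproducible.

What the generator does **not** emulate: GC/length bias, batch effects,
outlier samples, correlated genes, a GO DAG (term memberships are
independent uniform draws), or read-level artifacts. Passing benchmarks
therefore demonstrate correctness of the statistics under a clean NB
world, not robustness to real-data pathologies.

## Differential expression stand-in

The DE stage is intentionally minimal and fully documented rather than a
re-implementation of an NB GLM; a real DE table (any tool) can be
supplied instead and flows through the identical downstream path.

- **Size factors**: median-of-ratios — s_j = median over genes of
  K_gj / geomean_g, genes containing any zero excluded. Factors are
  reported unnormalized; only their ratios affect fold changes, and a
  c-fold rescaling of one library changes all fold changes by exactly
  nothing (zero-free genes).
- **Fold change**: log2 of the ratio of treated to control means of
  normalized counts. A pseudocount of 0.5 is added to *both* means only
  when either is zero, so strictly positive data keep exact ratios.
- **Test**: two-sample t on log2(normalized + 1). The default pools the
  group variances (Student). This is a deliberate choice: at 3 vs 3 the
  Welch–Satterthwaite degrees-of-freedom approximation is badly
  conservative — empirical size ≈ 0.036 at nominal 0.05 on *exactly
  normal* data (≈ 0.035 on the NB generator) — while the pooled test
  holds its size (≈ 0.050 in both cases). With equal group sizes and a
  shared design variance, pooling is also the statistically natural
  model. Welch remains available (`de_test(..., equal_var=False)`) for
  genuinely heteroscedastic designs and is oracle-tested. Genes constant
  across all samples get p = 1.
- **Multiplicity**: Benjamini–Hochberg step-up over *all* tested genes
  (no independent filtering) — simpler and slightly conservative
  relative to pipelines that pre-filter low-count genes.
- **Selection rule**: padj ≤ α (default 0.05) AND |log2FC| > log2 θ
  (default θ = 1.5), applied symmetrically in both directions; the
  fold-change comparison is strict, the p comparison inclusive. Raw
  (unshrunken) fold changes are thresholded.
- **Ranking**: ascending raw p, ties by larger |log2FC|, then gene id —
  a total, stable order, which the sweep requires.

Known limitation: with three replicates, a t-based per-gene test after
BH over thousands of genes has very little power at fixed thresholds —
typically a handful of selections, and a 2.64-fold focal effect usually
misses padj ≤ 0.05 (it still ranks in the top tier). This is not a bug
of the implementation but the statistical reality the threshold-free
sweep addresses; NB GLMs with information sharing across genes (the
standard tools) are out of scope here by design.

## The enrichment sweep

- **Universe**: genes present in both the ranked list and the annotation
  (annotation-restricted background). Terms with fewer than
  `min_term_size` (default 3) universe members are excluded — smaller
  terms produce unstable tails.
- **Step grid**: rank-based top-n steps at step_size (default 25), 2·25,
  …, up to the last universe gene with raw p ≤ max_alpha (default 0.5);
  the endpoint is always included. Rank steps stay well-defined under
  tied p-values, and the max_alpha cap stops the sweep before pure
  noise. Both knobs are configurable.
- **Test**: one-sided hypergeometric over-representation tail P(X ≥ k),
  summed in log space (logpmf + logsumexp) so extreme tails (p ≪ 1e-300
  territory in large universes) do not underflow.
- **Multiplicity**: BH across terms *within* each step (column-wise).
  The per-term score — the minimum adjusted p over steps, with the
  smallest step winning ties — is *not* further adjusted across steps
  and is labelled exploratory in the outputs. Steps are strongly
  dependent (nested selections), so a cross-step correction would be
  both awkward and very conservative; under the complete null the
  per-step BH keeps the realized false-discovery proportion ≤ 0.05-ish
  per step (measured ≈ 0.03 averaged over 50 null simulations).
- **Term selection**: ascending best adjusted p, ties by smaller best
  step, then term id. **Gene representation**: genes annotated to ≥ 1
  selected term, ordered by number of selected terms, then better DE
  rank, then id.
- **Heatmap**: cell(g, t) = −log10(best adjusted p of t) if g ∈ t else
  0 — each gene is shown at the maximum significance its processes
  attained anywhere in the sweep. An alternative cell semantic (the step
  index of best significance) was considered and rejected as less
  directly interpretable; the table form (`heatmap.tsv`) carries the
  same numbers as the image.

## Numerical and degenerate-input choices

- Hypergeometric p-values are exact (no normal approximation) and capped
  at 1 after exponentiation.
- BH is the textbook step-up (sort, cumulative minimum from the tail,
  cap at 1, unsort); vectors of length 0/1 pass through.
- An empty annotation, an annotation disjoint from the ranking, or a
  landscape with no eligible term raise typed errors rather than
  returning empty frames.
- Normalization requires at least one zero-free gene; otherwise a
  normalization-infeasible error is raised.
- All randomness flows from explicit integer seeds; identical
  config + seed reproduces every output byte-for-byte, and the run
  manifest (config + seed + versions) suffices to reproduce a run.

## Problem sizes

The bundled benchmarks run at 2,000 genes × 6 samples with 200 terms;
the multi-seed benchmarks use 50 seeds (focal-effect recovery, null
calibration) and 20 seeds (planted-term recovery). At these sizes the
full test suite and the benchmark drivers complete in a few minutes on a
single core. All sizes scale linearly in genes × steps.
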