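# Methods

This note documents the statistical conventions the package implements,
the generative model behind its synthetic data, the defaults and why
they were chosen, and what the test suite does and does not establish
about real data.

## Profiles and the divergence statistic

Per-gene HM signal is the log2 of the *mean* per-bin IP/input enrichment
ratio over a region (mean-then-log). When a nucleosome-occupancy track
is supplied, each bin is divided by it before averaging; with
proportional tracks the normalisation cancels exactly. Whether averaging
should precede or follow the log transform is a genuinely open
convention; mean-then-log was chosen and is isolated behind
`aggregate_region_signal`, so switching conventions touches one
function.

Z-scores use the population (divide-by-n) standard deviation, since the
normalising δ is a descriptive quantity over the full gene catalog, not
an estimate from a sample. μ and δ are computed over finite entries
only; missing entries stay missing, and pairs fall back to
pairwise-complete marks downstream. A mark with zero variance is a hard
error naming the mark — silently propagating a constant column would
poison every downstream correlation.

`D_HM = 1 − r` is computed over the marks finite in both members; at
least 3 shared marks and nonzero variance in both profiles are required,
otherwise the pair's score is missing and excluded from tests (never
imputed). The statistic is symmetric, lies in [0, 2], and is invariant
to common positive affine rescalings of both profiles.

Regions: the ORF, and the promoter defined as the 500 bp immediately
upstream of the strand-aware TSS (start on +, end on −), clipped at
position 1 and never overlapping the gene body.

## Statistical tests

* Randomized controls: `n` singleton pairs are drawn uniformly per
  replicate (genes may recur within a replicate — the simplest null
  consistent with drawing "the same number" of random pairs; a perfect
  matching would impose structure the null does not need). The observed
  scores are compared against the pooled null with a two-sided Wilcoxon
  rank-sum test; a per-replicate empirical p (fraction of replicate
  medians at or below the observed median) is reported as a diagnostic.
  The full design uses 10,000 replicates; tests and the acceptance
  script use hundreds, which is ample for the medians involved.
* Chromosome bias: Pearson χ² without continuity correction on the 2×2
  table {duplicate, randomized} × {same, different chromosome}, df = 1,
  with a matched-size randomized replicate as the comparison group.
* The same-vs-different-chromosome divergence comparison reports the
  Wilcoxon rank-sum p as primary and Student's t as secondary — the two
  appear interchangeably in this literature, so both are emitted.
* Physical distance is TSS-to-TSS separation (undefined across
  chromosomes); the distance–divergence relation is a plain Pearson
  correlation over same-chromosome pairs.
* Mode comparisons use Kruskal-Wallis (midranks, tie-corrected, as SciPy
  implements it); condition and type comparisons use pairwise two-sided
  Wilcoxon rank-sum tests.
* Mantel concordance: mark × mark correlation matrices are computed
  separately from the gene_a and gene_b sides of all pairs; the Mantel
  statistic is the Pearson correlation of their upper triangles, with
  significance from simultaneous row/column permutations of one matrix.
  With ≤ 5 marks all k! permutations are enumerated and the p-value is
  exact (identity included, no estimator correction); otherwise 9,999
  permutations are sampled and p = (b + 1)/(m + 1), two-sided on |r|, so
  p is never 0. Pairs are oriented canonically (lexicographic gene id);
  the statistic is insensitive to orientation in practice but the
  convention makes runs reproducible.
* Ka/Ks selection: strictly `Ka < 0.5` and `Ks < 2.0`, both finite;
  pairs with missing rates are excluded rather than treated as 0.
  Saturated Ks estimates are unreliable, and large Ka implies the pair
  is old enough that profile comparisons conflate divergence with
  annotation error.
* Expression divergence `E = 1 − r` of log2(FPKM + 1) vectors within a
  condition group mirrors the 1 − r form of D_HM, keeping the two
  divergences on one scale; this is the package's definition (the
  formula is not uniquely fixed by the literature it follows) and it is
  isolated behind `expression_divergence`.
* GO-overlap types I–V are decided in emptiness-first order (both empty
  → V; exactly one empty → IV; equal → I; intersecting → II; disjoint →
  III), which makes the five rules mutually exclusive and total and the
  classification symmetric under swapping the pair. Type IV is
  role-symmetric: either member may be the annotated one. Terms are
  compared as raw identifier sets — no ancestor propagation — because
  the classification is purely set-theoretic.
* Raw p-values are the primary output; the report adds a clearly
  labelled Benjamini-Hochberg column for readers who want FDR control,
  and never substitutes it.

## The synthetic-data generator

The generator emulates the analysis surface, not the raw assays: no
probe-level ChIP signal, no reads, no real sequence.

* Genome: 5 chromosomes of 1 kb genes every 2 kb; tandem pairs occupy
  adjacent gene slots, proximal pairs lie within 10 slots, WGD and
  transposed pairs land on one chromosome only with their configured
  probability (defaults 0.30 and 0.10), which produces both the
  same-chromosome excess of duplicates over random pairs and the
  tandem < proximal < transposed distance trend.
* HM profiles: each mark is bivariate normal between pair members on the
  z-score scale with correlation ρ drawn per pair around the mode's
  value (jitter SD 0.15, clipped to ±0.99). Mode defaults (tandem 0.65,
  proximal 0.60, WGD 0.50, transposed 0.30) reproduce the qualitative
  ordering of paralog similarity, and a +0.10 promoter boost makes
  promoter profiles more conserved than ORF profiles. Marks carry a
  two-block covariance across genes (active marks correlate 0.45 with
  each other, repressive marks — H3K9me2, H3K27me1/3 — likewise, with
  weak negative cross-correlation), giving both pair members the same
  co-occurrence structure; this is what the Mantel test detects. Under
  this model the expected pair divergence has the closed form
  E[D_HM] ≈ 1 − ρ + ρ(1 − ρ²)/(2K) for K marks, which the tests check.
  The bivariate-normal marginal is a modelling convenience: correlations
  are what the analysis consumes, and the normal form gives exact
  control and closed-form expectations.
* Ka/Ks: Ka = max(0, 0.03 + s·(1 − ρ) + noise) with coupling slope
  s = 0.25, and Ks a noisy 2–5× multiple of Ka, so epigenetic and coding
  divergence are positively coupled and nearly all pairs pass the
  selection filter, as in the real catalog.
* Expression: pair members share a common per-sample profile plus
  independent noise whose SD is the condition shift (Normal 0.6, Stress
  0.6, CM_mu 1.2) scaled by (0.5 + c·(1 − ρ)) with coupling c = 1. This
  yields E_CM_mu > E_Normal ≈ E_Stress and a positive D_HM–E
  correlation, both with known sign. Sample groups default to the study
  sizes 18/20/50. Abundances are exp2 of a truncated normal latent, an
  FPKM-like right-skewed scale.
* GO sets realise a functional type sampled per mode; the default
  mixtures put half of WGD pairs in Type II (partial overlap) and tilt
  single-gene modes progressively toward disjoint/unannotated types.
  Identifiers are synthetic ("GO:SYNTH:k"); there is no ontology.
* Determinism: one `numpy` Generator seeded from the config; identical
  configs give byte-identical written datasets. The injected parameters
  (per-pair ρ, type, couplings) are exported in a truth sidecar for
  recovery tests.

What passing tests show — and do not. Parameter-recovery and calibration
tests demonstrate that the estimators and tests are correct and unbiased
*under this generative model*. Real enrichment ratios are not normal,
real marks are not exchangeable across genes, real expression noise is
not homoscedastic, and real GO annotation is incomplete in structured
ways; agreement on synthetic data therefore validates the machinery, not
any biological claim. Quantities that depend on the real genome's pair
placement and real ChIP data (e.g. the published per-mark correlation
table or the published χ² for chromosome bias) are intentionally out of
scope.

## Problem sizes

The default generator reproduces the full study scale (27,500 genes,
8,111 pairs, 88 samples) and runs in seconds; randomization ensembles
dominate the cost. The test suite and `scripts/acceptance.py` use
scaled-down designs — 810–8,000 pairs, hundreds of randomization
replicates, 9,999 Mantel permutations — chosen so the whole suite runs
in well under a minute of compute per heavy test while keeping every
Monte-Carlo tolerance comfortably satisfied. `null_replicates` stores
one score vector per replicate; at the full 10,000 × 8,111 design this
is ~0.6 GB per analysis, so study-scale runs should use the pipeline's
TSV/JSON outputs rather than holding several results objects alive.

## Known limitations

* The expression-divergence formula is a package convention (see above);
  alternatives (fold-change- or distance-based E) would need their own
  calibration.
* The Mantel test permutes marks, so with 10 marks the smallest sampled
  p is bounded by the permutation count and exhaustive enumeration is
  impractical (10! ≈ 3.6 M); the sampled estimator with the add-one
  correction is used instead.
* `validate_inputs` checks id consistency and duplication-class
  conflicts, not biological plausibility.
* The generator couples Ka and expression noise to the *injected* pair
  correlation, not to the realised profiles; at small pair counts the
  observed D_HM–Ka correlation is noisier than the injected slope
  suggests.
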