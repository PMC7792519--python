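# paralog-epidiv

Epigenetic divergence analysis of duplicate gene pairs, built around the
study design used for *Arabidopsis thaliana* paralogs: per-gene histone
modification (HM) profiles over ten marks (H2Bub, H3K4me1/2/3, H3K9ac,
H3K9me2, H3K27me1/3, H3K36me3, H3K14ac), a pairwise divergence statistic,
chromosome-aware randomized controls, and couplings with coding-sequence
divergence (K_A/K_S), expression divergence and GO-overlap functional
divergence.

The package is for researchers studying how chromatin state evolves after
gene duplication — whole-genome (WGD), tandem, proximal and transposed
duplications — who have gene-level enrichment tables rather than raw
ChIP or RNA-seq reads.

## The statistic

For each gene and each of the ten marks, the log2 average enrichment ratio
(optionally nucleosome-normalised) over a region — the ORF, or the 500 bp
promoter upstream of the strand-aware TSS — is standardised across genes,

&nbsp;&nbsp;&nbsp;&nbsp;*Z* = (χ − μ) / δ,

with μ and δ the mean and population standard deviation over all genes.
A gene's HM profile is its 10-mark z-score vector, and the divergence of a
duplicate pair is

&nbsp;&nbsp;&nbsp;&nbsp;*D*<sub>HM</sub> = 1 − *r*,

where *r* is the Pearson correlation of the two profiles; subscripts O/P
denote ORF and promoter (*D*<sub>HM–O</sub>, *D*<sub>HM–P</sub> ∈ [0, 2]).
Observed pair divergences are compared against nulls of randomly drawn
singleton pairs (10,000 randomizations in the full design; Wilcoxon
rank-sum), including a variant constrained to different chromosomes to
control for chromosome bias (tested by Pearson χ², df = 1). Expression
divergence *E* is defined analogously as 1 − *r* of log2(FPKM + 1)
vectors within each condition group (Normal / Stress / chromatin-modifier
mutants, CM_mu), and functional divergence is classified into Types I–V
from the overlap of the two genes' GO term sets.

Because the original ChIP-chip/RNA-seq matrices are not bundled, the
package ships a synthetic-data generator
(`paralog_epidiv.simulate`) whose defaults mirror the study design
(8,111 pairs: 4,293 WGD / 2,130 tandem / 784 proximal / 904 transposed;
88 expression samples: 18 Normal / 20 Stress / 50 CM_mu) with
controllable pair correlations, couplings and GO-type mixtures, so every
stage is testable against known injected truth.

## Worked example

```python
from paralog_epidiv import SyntheticConfig, generate_dataset, DuplicateHMDivergence

config = SyntheticConfig(
    genes_per_chromosome=800,
    n_pairs_by_mode={"WGD": 429, "tandem": 213, "proximal": 78, "transposed": 90},
    seed=7,
)
dataset = generate_dataset(config)
model = DuplicateHMDivergence.from_dataset(dataset)
results = model.fit(n_randomizations=500, mantel_permutations=9999, seed=7)
print(results.summary())
```

prints

```
Duplicate-gene HM divergence analysis
======================================
pairs: 810   singletons: 2380
by mode: WGD=429, tandem=213, transposed=90, proximal=78
median D_HM-O: 0.4232
median D_HM-p: 0.3262
randomized control [ORF]: observed median 0.4232 is lower than null (Wilcoxon p=4.68e-218, 500 replicates)
randomized control [promoter]: observed median 0.3262 is lower than null (Wilcoxon p=3.27e-289, 500 replicates)
randomized control [ORF_different_chromosomes]: observed median 0.5084 is lower than null (Wilcoxon p=1.39e-77, 500 replicates)
randomized control [promoter_different_chromosomes]: observed median 0.3890 is lower than null (Wilcoxon p=2.67e-113, 500 replicates)
chromosome bias: chi2=198.9812, df=1, p=3.48e-45
divergence by mode [ORF]: Kruskal-Wallis H=59.94, p=6.06e-13
divergence by mode [promoter]: Kruskal-Wallis H=81.81, p=1.25e-17
Mantel concordance [ORF]: r=0.997, p=0.0004 (9999 permutations)
Mantel concordance [promoter]: r=0.997, p=0.0001 (9999 permutations)
corr(D_HM-O, KA): r=0.334, p=1.4e-22 (n=810 after Ka/Ks filter)
corr(D_HM-p, KA): r=0.367, p=2.73e-27 (n=810 after Ka/Ks filter)
corr(D_HM-O, KS): r=0.277, p=9.3e-16 (n=810 after Ka/Ks filter)
corr(D_HM-p, KS): r=0.287, p=8e-17 (n=810 after Ka/Ks filter)
corr(D_HM-O, E_Normal): r=0.256, p=1.34e-13
corr(D_HM-p, E_Normal): r=0.233, p=1.82e-11
E Normal vs Stress: medians 0.236/0.242, Wilcoxon p=0.986
E Normal vs CM_mu: medians 0.236/0.561, Wilcoxon p=3.29e-201
E Stress vs CM_mu: medians 0.242/0.561, Wilcoxon p=1.4e-196
WGD vs single-gene x Type II: Fisher p=1.71e-11
```

Reading the output: duplicate pairs are markedly less divergent than
random singleton pairs (the "lower than null" lines), even after forcing
both members of the control pairs onto different chromosomes; divergence
differs among duplication modes with transposed duplicates most divergent;
pair members share the same mark co-occurrence structure (Mantel r ≈ 1);
D_HM rises weakly with K_A/K_S (epigenetic divergence tracks coding
divergence) and with expression divergence; and expression divergence is
specifically elevated in chromatin-modifier mutants (CM_mu) while Normal
and Stress are indistinguishable. WGD pairs are enriched for partial GO
overlap (Type II).

The same analysis runs from the shell on real or simulated input files:

```bash
paralog-epidiv simulate --config cfg.yaml --out data/ --seed 1
paralog-epidiv validate --config cfg.yaml
paralog-epidiv run --config cfg.yaml --out results/ --seed 1
paralog-epidiv report --report results/report.json
```

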