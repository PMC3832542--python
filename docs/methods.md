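# Methods

## The RNA stability score

For a sample with expression values for N classified genes, all N values
are ranked ascending (1..N, ties receive the average of their rank span)
and the score is the difference between the mean rank of the long-lived
group and the mean rank of the short-lived group. Properties used
throughout the tests: invariance to strictly monotone transformations of a
sample's expression values (so array normalization choices that preserve
order do not matter), the exact bound |RS| ≤ N/2 with equality iff the two
groups separate completely, and zero expectation under exchangeability.

Only classified genes participate in the ranking. This makes the N/2 bound
exact and the score comparable across half-life sources with different
coverage; including unclassified genes would rescale the score by an
arbitrary, source-dependent amount. Duplicate probe rows for one gene are
collapsed by their mean before ranking.

### Gene classification schemes

- `half_life_threshold` (default): long-lived iff half-life ≥ 4 h. The
  4-hour boundary is the conventional cut separating stable from unstable
  transcripts in mammalian half-life compendia, and the boundary value
  itself counts as long-lived.
- `decay_rate_mean`: long-lived iff the relative decay rate is below the
  across-gene mean. Slower decay means a longer-lived transcript; because
  published decay-rate tables differ in sign conventions, the rule can be
  flipped with `long_when_below_mean=False`.
- `housekeeping`, `coding`: alternative groupings that exploit the strong
  tendency of housekeeping and protein-coding transcripts to be stable;
  useful as concordance checks on the primary half-life grouping.

## Association scan

Per SNP, ordinary least squares of the score on minor-allele dosage with an
intercept, sex, and the top genotype principal components; two-sided t test
on the dosage coefficient. SNPs with complete dosages are fit in one
vectorized Frisch–Waugh–Lovell pass (residualize phenotype and dosages on
the covariates, then simple regression), which is algebraically identical
to the per-SNP fit; SNPs with missing dosages fall back to per-SNP OLS with
pairwise deletion. Degenerate fits are flagged, never silently assigned
p = 1: a constant dosage yields an undefined p, a perfect fit yields
se = 0.

Defaults mirror standard GWAS practice on expression panels: MAF filter at
0.01 (SNPs with cohort MAF ≤ 1% excluded; the frequency is recomputed in
each analysis cohort, so the filter — like minor-allele orientation — is
cohort-relative), 5 principal components, two-sided p-values.

PCA uses the Patterson/Eigensoft normalization: rows mean-centered, missing
dosages mean-imputed, scaled by sqrt(p̂(1−p̂)) with the shrunken estimate
p̂ = (1 + Σdosages)/(2 + 2n), which keeps monomorphic rows finite (they are
zeroed and contribute nothing). Component signs are arbitrary; tests are
sign-invariant.

The genomic inflation factor is λ = median(χ²₁(1−p))/0.45494. The package
reports it per scan; the null simulations show λ ≈ 1 with PCs included and
λ ≫ 1.05 when structure is left uncorrected and the phenotype carries a
population-level shift.

### Permutation testing

Genome-wide significance by the min-p scheme: the phenotype vector is
shuffled across samples, the full scan re-run, and the minimum p recorded;
the permutation p is the fraction of null minima at or below the observed
minimum. Covariates stay attached to their samples — only the phenotype
moves — which preserves the genotype–covariate structure and is the
conservative choice under stratification. The estimator admits an exact
zero (0/n_perm); summaries print it as "< 1/n_perm" while the raw count is
kept.

## eQTL mapping

Spearman rank correlation (average-tie ranks on both vectors, two-sided p
via the t approximation on n − 2 df) of a SNP's dosage against gene
expression. The trans scan covers all genes and controls FDR with
Benjamini–Hochberg at 0.1 over the genes actually tested; the sign of rho
is retained so positively-correlated discovery subsets are recoverable. The
cis scan restricts to genes on the SNP's chromosome whose TSS lies within
half a window of the SNP (window 1 Mb, i.e. ±500 kb, boundary inclusive);
the minimum-p cis gene is the candidate mediator. The TSS anchor is a
configuration choice — gene-body anchoring would enlarge the effective
window for long genes without changing the method.

## Knockdown analyses

Score-level: two-sided paired t test across replicates (knockdown vs
control), and pooled-variance two-sample t when the pairing is not
meaningful. Gene-level: natural-log expression ratios treated/control per
gene, compared between long- and short-lived groups by a two-sided Wilcoxon
rank-sum test (exact null distribution when both groups have ≤ 20 genes,
normal approximation otherwise). Adding a constant to all log-ratios — e.g.
a global scaling of one condition — leaves the rank-sum p unchanged; this
invariance is asserted in the tests. One-way fixed-effects ANOVA compares
scores across the genotype classes present (with two classes, F = t²
exactly).

## Synthetic-study generator

The generator emulates the structure of a multi-population expression +
genotype panel:

- **Genotypes.** Per SNP, an ancestral frequency uniform on `maf_range`
  (default 0.05–0.5); per-population frequencies Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `fst` (default 0.1, two
  populations — divergence of the order seen between continental human
  populations); dosages Binomial(2, p_pop), i.e. Hardy–Weinberg within
  population; independent SNPs placed uniformly on a 5-chromosome synthetic
  genome. Sex is Bernoulli(0.5).
- **Half-lives.** A two-component log-normal mixture (medians 12 h and 2 h,
  log-sd 0.5) truncated at the 4 h boundary so group sizes are exact
  (default half the genes long-lived). The components span the range
  typical of mammalian mRNA decay. Housekeeping and coding flags are
  enriched among long-lived genes at 3:1 odds (base rates 0.2 and 0.5 in
  the short group), reflecting the empirical association between stability
  and housekeeping/coding status; AU-rich-element target flags are enriched
  among short-lived genes.
- **Expression.** log-expression = gene baseline (Normal(5, 1)) +
  effect_size × causal dosage × [long-lived] + optional sex and
  population shifts on long-lived genes + Normal(0, 0.5) noise,
  exponentiated. A single causal SNP acting additively on the log scale is
  the minimal generative model consistent with a trans-acting stabilizer
  under genetic control; `causal_snp_index=None` gives the global null.
- **Knockdown.** Paired control/knockdown replicate columns; knockdown
  subtracts a fixed shift from the log-expression of long-lived genes only,
  emulating the loss of a stabilizer whose targets are predominantly
  stable transcripts.

Each generator draws from its own RNG stream derived from the config seed,
so outputs are bit-reproducible and mutually independent given the seed.

**Default effect size (0.026).** The per-dosage shift was calibrated once,
by simulation under the recovery-study conditions (2 populations, Fst 0.1,
200 samples, 2000 SNPs, 1000 genes), to give approximately 80% power to
detect the causal SNP at the Bonferroni-adjusted 0.05 level (realized
power ≈ 0.82, top-SNP recovery ≈ 0.92 across seeds). In score units this
corresponds to a shift of roughly 6–7 rank positions per dosage unit —
deliberately subtle at the single-gene level.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent, so multiple-testing behaviour is exactly Bonferroni-like,
whereas real panels are effectively less multiple), probe- and batch-level
artifacts, expression correlation between genes beyond the shared causal
effect, mixed ancestry/admixture, and any relation between a gene's
half-life and its baseline expression level. Passing tests therefore
demonstrate correctness and calibration of the statistics under the assumed
model, not robustness to array artifacts or LD structure.

## Numerical and design choices

- Tie handling in all ranks: average ranks (preserves rank-sum identities).
- Positions are 1-based; cis windows and VCF coordinates agree.
- Minor-allele orientation from VCF input is decided per cohort (ALT
  frequency > 0.5 flips the dosage and swaps the recorded alleles); an
  allele can be minor in one population and major in another, so the
  report records which allele was counted.
- BH adjustment is the standard step-up (delegated to statsmodels);
  Fisher's test is the conditional hypergeometric two-sided exact test;
  Spearman p uses the t approximation throughout — at the scan sizes the
  package targets (n ≥ ~40), the approximation error is far below the
  FDR resolution.
- Permutation p and Bonferroni p are reported alongside each other; they
  answer different questions (empirical genome-wide vs worst-case
  family-wise).
- Simulation sizes in the test suite (up to 2000 SNPs × 200 samples ×
  1000 genes, 50 replicate seeds, 200 permutations) were chosen so each
  statistical check has enough resolution for its assertion while the full
  suite stays interactive to run.

## Known limitations

- Replicate-level standard errors only for knockdown scores; no
  within-sample resampling scheme is provided.
- The scan is plain OLS: no mixed-model correction, so extreme relatedness
  beyond what PCs capture would inflate λ.
- The VCF reader covers the GT-only biallelic dialect the pipeline writes,
  not the full VCF specification.
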