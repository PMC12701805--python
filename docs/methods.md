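# Methods

`bovqtl` re-implements, as one coherent and testable pipeline, the
statistical machinery of an integrative body-weight study in beef
cattle: mixed-model GWAS, gene-based and multi-trait association, an
iHS selective-sweep scan, cis-eQTL mapping with permutation
calibration, TWAS, colocalization, SMR, annotation enrichment and
methylome feature calling.  Because the study's animal data cannot be
redistributed, every stage is exercised against a synthetic cohort
whose causal structure is known exactly; all quantitative claims in
the test suite are claims about recovering that planted truth.

## The synthetic cohort

**Haplotypes.** A founder pool of H haplotypes (default 30) is built
per chromosome from a latent Gaussian AR(1) over sites, thresholded at
each site's target allele frequency (drawn uniform on [0.05, 0.95]).
The autocorrelation (default 0.9 per site) is the single LD knob;
thresholding preserves the marginal frequencies, which matters
downstream because the iHS standardization bins scores by derived
allele frequency and needs neutral variants across the whole frequency
range.  (A literal allele-copy Markov chain was tried first and
rejected: exponential smoothing of the target frequencies pulls every
marginal toward 0.5.)  Individuals are recombinant mosaics of founder
draws with a per-bp switch probability (default 5e-7, giving segments
of a few megabases).  Sites that come out monomorphic are given a
single flipped haplotype, emulating a cohort-ascertained call set.
The ancestral allele equals REF by construction and is written to the
VCF's AA INFO tag; a DR2 INFO value drawn from Beta(20, 1.5)
(mean ~0.93, as imputation quality summaries typically report) feeds
the imputation-quality filter.

**Partial sweep.** One founder haplotype is driven to a target
frequency (default 0.8) over a window (default 500 kb) around a core
site: a fixed fraction of haplotypes copy that founder unbroken across
the interval.  Derived carriers therefore share one long haplotype —
the signature iHS integrates — while EHH decays normally outside the
interval.  The realized core frequency is exact by construction.

**Traits.** Each of n_traits (default 3) is a sum of a compact
pleiotropic block, a polygenic background (default 30 variants with
effect sd 0.15), farm/sex fixed effects, and Gaussian noise scaled so
the realized genetic/total variance ratio equals trait_h2 (default
0.4) exactly in-sample.  Cross-trait effect and residual correlations
both follow trait_corr (default 0.6 off-diagonal).  The block
(default 100 kb, 5 causal variants) is hierarchical: its highest-MAF
causal is the *mechanism lead*, carrying a uniform effect of
2.5 x effect_scale on every trait, with the remaining satellites drawn
at 0.6 x effect_scale.  This plants the textbook colocalisable locus —
one dominant shared signal — which the third acceptance stage
(COLOC/SMR) is designed to find; with five equal-effect causals the
locus lead is a coin flip and colocalization correctly, but
unhelpfully, reports distinct causal variants.

**Expression.** log2(TPM+1) = baseline + cis effects x dosage +
hidden-factor term + N(0, 0.5) noise, back-transformed and floored at
zero.  A configurable fraction of genes (default 0.30) carries one cis
eQTL (effect ~ N(0, 0.6) log2 units) within 1 Mb of the TSS; the gene
nearest the pleiotropic block receives its eQTL at the mechanism lead
with effect 1.0, completing the variant -> expression -> trait chain.
Hidden factors have geometrically decaying strengths (0.7 per
component) so the factor subspace is identifiable without rotation.

**Methylome.** CpG positions are the actual CG dinucleotides of a
generated sequence: a CpG-depleted background (90% of CG pairs broken)
with embedded CpG/GC-rich islands, half of which sit inside planted
hypomethylated regions.  Per-sample methylation levels are Beta draws
(concentration 30) around 0.10 (hypomethylated) or 0.80 (background);
counts are Binomial at Poisson(20) coverage.  Annotation tracks are
TSS-enriched peaks, chromatin-state labels, and non-overlapping TADs
tiling each chromosome.

What the generator does *not* emulate: realistic bovine demography or
coalescent genealogies, genotyping error, allelic mapping bias in
expression, non-CpG methylation, read-level data.  Passing tests
demonstrate that each estimator recovers its target under a correctly
specified generative model at desk scale; they do not certify
robustness to the misspecifications real data add.

## Association stack

The GWAS is the one-GRM mixed linear model in the MLMA convention:
variance components are fitted once per trait by single-component REML
(eigendecomposition of the GCTA-style GRM, 1-parameter bracketed
search over log lambda, profiled residual variance), then reused for
every variant, making the scan one eigendecomposition plus O(M) GLS
fits.  Wald p-values are two-sided normal; 5e-8 and 1e-6 label
genome-wide and suggestive hits.  Leave-one-chromosome-out GRMs are
available behind a flag but off by default.  Conditional analysis
appends the target variant's dosage to the covariates and excludes it
from the scan, raising on collinearity.  Per-variant genetic variance
explained is 2p(1-p)beta^2/sigma2_a x 100%.

The multi-trait statistic is t' V^-1 t per variant, with V the Pearson
correlation of signed t-values over all scanned variants, shrunk
toward the identity by 5% to guard against ill-conditioning (an option
restricts V estimation to |t| < 2 variants); df = n_traits, Bonferroni
significance at 0.05/M.

Gene-based association uses gene-body +/-50 kb windows.  SNP-wise Mean
sums 1-df chi-square quantiles of the member p-values and calibrates
against sum(lambda_j chi2_1) via Satterthwaite moment matching on the
eigenvalues of the in-sample LD matrix (clipped at 0, tolerance 1e-8);
SNP-wise Top compares the minimum p with Monte-Carlo draws from
MVN(0, R).  The two models are combined by a Bonferroni rule
(min(1, 2 min(p))) — the upstream tool's exact aggregation is
undocumented, so the transparent conservative rule is used — and genes
are called at 0.05/n_genes.

## Sweep scan

EHH at a marker is the probability two random carrier haplotypes of
the core allele are identical over the intervening segment, computed
by prefix grouping (sum of C(n_g, 2)/C(n_carriers, 2)); an exhaustive
brute-force pairwise-identity oracle pins this formula exactly in the
tests.  iHH integrates EHH by trapezoid over physical distance
outward until EHH < 0.05, skipping cores that hit a > 800-kb gap or a
chromosome end first.  uniHS = ln(iHH_ancestral/iHH_derived) is
standardized to mean 0/sd 1 within 100 equal-width DAF bins (sparse
bins merged with neighbours).  Candidate windows are non-overlapping
50-kb tiles (anchored at 0) whose mean |iHS| ranks in the top 1% of
occupied windows (int(n x 0.01) windows, matching the published
49,410 -> 494 arithmetic) and which hold strictly more than 10 SNPs.
The inner walk is numba-compiled; a full two-chromosome scan of 10k
variants x 200 haplotypes takes ~3 s.

## cis-eQTL stage

Genes pass the expression filter (TPM >= 0.1 in >= 20% of samples,
boundaries inclusive).  Normalization is rank-based inverse-normal per
gene with the Blom offset (rank - 3/8)/(n + 1/4), ties by average
rank; ranks are taken from the input values (see the module docstring
— the cross-sample quantile normalization, which is also provided, is
monotone within samples, not genes, and would only inject spurious
ties into a transform that replaces its values anyway).  Hidden
technical covariates are the top expression PCs (default 10, with a
deterministic sign convention) plus 2 genotype PCs; PCA stands in for
latent-factor inference because the screening criterion — variance
explained plateauing — is itself variance-based, and PCs are exactly
reproducible.

The nominal scan tests every variant within 1 Mb of the TSS by a
covariate-residualized slope test (df = n - 2 - n_covariates).
Gene-level calibration permutes expression 1000 times (fixed count
rather than an adaptive 1000-10,000 schedule, for determinism; the
Beta approximation supplies resolution below 1/1001), fits Beta(a, b)
to the permutation minimum p by ML (method-of-moments fallback,
flagged), and reports both the Beta-CDF empirical p and the direct
count.  eGenes are Benjamini-Hochberg at FDR 0.05; each eGene's
per-variant nominal threshold is the Beta quantile of the global
empirical-p cutoff.  aFC fits mu + beta x dosage on covariate-
residualized linear-scale TPM and reports log2(1 + 2 beta/mu), capped
at +/-6.64 and flagged missing when mu <= 0.  Independent signals use
forward-stepwise conditioning with a backward refinement pass, gated
on the eGene flag and the per-gene threshold.  pi1 estimates the
replication fraction by Storey's method: pi0(lambda) on the grid
0.05..0.95, cubic smoother, read off at the top of the grid (true
extrapolation to lambda = 1 is unstable).

## TWAS

Genes with >= 10 polymorphic cis variants are screened by cis-GRM REML
with a likelihood-ratio test against sigma2_a = 0 under the boundary
null (1/2 chi2_0 + 1/2 chi2_1); genes with h2 > 0 and p <= 0.05
proceed.  Four weight models are trained on standardized cis dosages:
single best eQTL (top1), ridge BLUP with penalty m(1-h2)/h2, lasso and
elastic net (mixing 0.5) with 3-fold inner-CV penalties on a short
alpha path.  (A fifth, MCMC-based sparse mixed model is deliberately
omitted.)  The outer 5-fold CV accuracy is the adjusted held-out
coefficient of determination — explained variance, not squared
correlation, so that overfit or anti-predictive models score negative
and noise genes are dropped.  The best model per gene predicts
expression into the association cohort; the trait is regressed on the
prediction with BH control at FDR 0.05 per trait.  With the top1 model
this is algebraically the single-variant association test, which the
suite asserts to 1e-8.

## Colocalization and SMR

Per variant and dataset the Wakefield log-ABF is
0.5[log(1-r) + r z^2], r = W/(V+W), with prior effect sd 0.15 for both
quantitative datasets.  Hypothesis scores sum single-variant
configurations (H1, H2), ordered distinct pairs (H3, via
exp(S1+S2) - exp(S12) in log space) and shared variants (H4), with
priors p1 = p2 = 1e-4, p12 = 1e-5, normalized by log-sum-exp; the
suite pins the posteriors to a literal configuration enumeration at
1e-10.  A gene-trait pair colocalizes at PP.H4 > 0.8.  GWAS input
regions are cis windows whose minimum GWAS p is <= 1e-5.  SMR uses the
top cis-eQTL passing the gene's nominal threshold as instrument:
T = z_g^2 z_e^2/(z_g^2 + z_e^2) against chi2_1, b_xy = beta_g/beta_e,
BH across genes per trait.  No heterogeneity (HEIDI-style) test is
performed.

## Enrichment

One permutation engine serves GWAS-signal-in-track,
GWAS-signal-in-eVariant-set, and eQTL-in-annotation questions:
observed overlap proportion versus draws of equal-size variant sets,
by default matched within 2%-MAF bins (both GWAS hits and eQTLs are
frequency-biased).  The two-sided empirical p around the permutation
mean uses mid-p tie handling — overlap counts are discrete, and
counting ties fully makes the null p distribution measurably
conservative (mean ~0.58 instead of 0.5); with half-weight ties the
null is uniform and the 1/(n_perm+1) floor is preserved.  TAD
co-occurrence is one-sided (excess): each eGene-eVariant pair is
permuted to a random tested variant at the same |TSS distance|
(+/-10 kb, doubled when no match exists) from a random gene's TSS,
5000 permutations.

## Methylome

CpG islands: 500-bp windows at 100-bp steps marked when GC >= 0.55 and
ObsCpG/ExpCpG >= 0.65 (Exp = #C x #G / L; inclusive thresholds; N
counts as non-GC), merged, then trimmed in 10-bp steps until the whole
region satisfies both criteria at >= 500 bp, else discarded — a
deterministic slide-merge-trim scan with the standard thresholds.
An island is experimentally supported when >= 5 CpGs at coverage > 5
inside it show coverage-weighted mean methylation < 0.30 in at least
one WGBS sample.

HMRs: CpGs with >= 10x coverage enter a two-state HMM with
beta-binomial emissions, trained by Baum-Welch from a fixed
initialization (state means 0.1/0.8, concentration 10,
self-transition 0.9; no random restarts, for reproducibility) with
weighted Nelder-Mead M-steps for the emission parameters; the
log-likelihood path is recorded and asserted non-decreasing.  Hypo
state is enforced as the lower-mean state after every iteration.
HMRs are maximal posterior-hypo runs, split wherever consecutive CpGs
are more than the desert limit apart (10 kb, the reading of the
upstream tool's "10-kb window size"); per-sample calls are merged by
interval union (pooled counts are available behind a flag).

## Orchestration and determinism

`pipeline.run_pipeline` executes the stages in dependency order from a
single `PipelineConfig` (YAML-loadable), recording per-stage parameter
hashes and output SHA-256 digests in `manifest.json`; disabling a
prerequisite makes dependents refuse to run.  One global seed fans out
to every stochastic operation through named SHA-256 substreams
(`core.substream`), so toggling one stage never shifts another's
stream, and a rerun reproduces every output byte-for-byte.  The
public face of the package is the importable API plus the `examples/`
scripts; the `bovqtl` console command is a thin wrapper that runs the
full pipeline from a config file.

## Problem sizes

The default cohort (400 individuals, 2 x 10-Mb chromosomes at ~5-kb
variant spacing, 300 genes, 3 traits) is the package's standing
desk-scale analogue of the study design (1577 genotyped animals, 227
muscle transcriptomes, 43 traits, 10.2M imputed SNPs).  Tests use
purpose-built sizes per claim: n = 1000 for heritability recovery,
n = 200 for eQTL slope recovery, 2 x 10-Mb chromosomes at 2-kb spacing
for the 20-replicate sweep-recovery experiment (the >10-SNP window
filter needs that marker density), and a 1000-individual cohort with a
300-sample expression subset for the end-to-end mechanism chain.

## Known limitations

- Colocalization assumes at most one causal variant per dataset per
  region; multi-signal loci resolve to H3 by design.
- The Satterthwaite calibration of SNP-wise Mean is exact only when
  all LD eigenvalues are equal; under strong LD it is approximate.
- The empirical-p machinery (permutations, enrichment) bottoms out at
  1/(n_perm+1).
- REML is single-component; no dominance, epistasis or GxE.
- pi1 inherits the endpoint variance of the pi0 smoother (sd ~0.03 at
  5000 p-values) and is coarse below a few hundred p-values.
- Expression-PC covariates estimated on the analysis matrix leak a
  small genotype-correlated component from strong eQTL genes into
  other genes' residuals, mildly inflating gene-level empirical
  p-values on dense gene sets (the analogue of latent-factor
  over-correction); the calibration tests quantify the clean-design
  behaviour.
- The iHS scan skips cores whose EHH has not decayed at a chromosome
  end rather than truncating the integral (configurable), so edge
  windows are sparser than interior ones.
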