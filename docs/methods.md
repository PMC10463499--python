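# Methods

## Scope and data model

`rumenlink` analyses a cohort of individuals with three aligned layers:
an individuals × SNPs additive genotype matrix (coded 0/1/2, missing
allowed), a samples × genera abundance table (counts or relative, with
phylum/genus labels), and a phenotype with categorical covariates
(birthplace, rearing season). All stages operate on these containers; the
pipeline (`run_all`) wires them in the order features → network → kinship →
variance components → association → scenario integration and writes TSV
outputs plus a manifest (seed, config hash, per-stage filter counts), so a
run is reproducible from its config alone.

## Microbial features

Counts are optionally rarefied to a fixed depth by sampling without
replacement (multivariate hypergeometric); samples below the depth are
dropped with a warning rather than resampled — the dialect used by the
common amplicon toolchains. ASV-level QC keeps features present in ≥ 3
samples with total count > 5. Genus-level QC on relative abundances drops
unclassified genera and requires mean relative abundance > 1e-6 together
with occurrence in strictly more than 3 samples. "0.0001%" in the original
filter is read as the proportion 1e-6 (the percent sign is taken literally).

Prevalence (fraction of samples with abundance > 0) partitions genera into
quantitative traits (prevalence ≥ 60%, CLR-transformed), binary
presence/absence traits (1.5% ≤ prevalence < 60%) and an excluded rare tail
(< 1.5%). The 60% boundary itself is assigned to the quantitative class: the
verbal rule ("less than 60% … binary, more than 60% … quantitative") leaves
exactly-60% unassigned, and `>=` makes the partition deterministic.

The CLR transform is `log(x + pc) - mean(log(x + pc))` per sample with a
default pseudocount of 1e-6 on relative abundances (configurable); rows of
the output sum to zero by construction. Alpha diversity uses the
bias-corrected Chao1 `S + F1(F1-1)/(2(F2+1))` (classic variant behind a
flag), the standard ACE estimator with rare/abundant cutoff 10 (when
coverage is undefined because every rare individual is a singleton, ACE
falls back to Chao1), and Shannon entropy in nats. PCoA is classical metric
MDS of Bray-Curtis distances via double-centred Gower eigendecomposition;
negative eigenvalues are ignored in the variance-explained denominator (no
Cailliez correction) and axes are scaled by the square root of their
eigenvalue.

## Co-occurrence network and keystone taxa

Genera with summed relative abundance < 1e-4 or prevalence < 1.5% are
excluded, then all-pairs Spearman correlations are computed on CLR values.
P-values use the tie-corrected t approximation; for fewer than 10 samples an
exact permutation enumeration replaces it. Benjamini-Hochberg adjustment
runs over every tested pair, and edges require |r| > 0.6 AND adjusted
p < 0.05. Modules come from Clauset-Newman-Moore greedy modularity
maximisation (deterministic; seeded Louvain available), with isolated nodes
as their own modules. Zi is the within-module degree z-score (population SD
over module members; 0 when the SD is 0) and Pi = 1 − Σ (k_m/k)²; the
four classes use strict inequalities at 2.5 / 0.62, so boundary values fall
to the lower class, and every non-peripheral node is flagged keystone. Core
genera are those with prevalence exactly 1.

## Relationship matrices and Mantel test

Genotype QC keeps biallelic autosomal SNPs with MAF ≥ 0.05 and missingness
≤ 0.3 (both configurable). The GRM is the Yang et al. estimator —
allele-frequency-standardised cross-products off the diagonal and the
`1 + [x² − (1+2p)x + 2p²]/2p(1−p)` form on the diagonal — with missing
genotypes mean-imputed to 2p per SNP beforehand. This estimator is not
guaranteed positive semidefinite at small n; the REML and GWAS code treat it
as an indefinite kernel and keep the working covariance positive definite
(see below). The MRM is `ZZ'/m` over column z-scored (sample SD)
abundances, dropping zero-variance taxa; its trace is n − 1 identically.
Genetic PCs are the top GRM eigenvectors scaled by the square root of their
eigenvalues, with a deterministic sign convention.

The Mantel test correlates the off-diagonal upper triangles of the two
relationship matrices directly on the similarity scale (no conversion to
distances), with a one-sided upper-tail p from simultaneous row/column
permutations and the +1 correction, p = (#{r_perm ≥ r_obs} + 1)/(n_perm+1);
an exact mode enumerates all n! permutations for small n.

## REML variance components

Models 1–3 share `y = Xb + Σ u_k + e` with `u_k ~ N(0, sigma2_k K_k)`. The
fixed design is an intercept, one-hot factors (first level reference) and
genetic PCs (5 for heritability scans, 3 for association). The general
fitter runs EM updates for the first 3 iterations, then average-information
Newton steps with step halving; candidate points where V loses positive
definiteness (possible with the indefinite Yang GRM) are rejected during the
line search. Components proposed negative are truncated at a floor of
1e-6 × var(y) and fixed (reported as 0) if they stay there. Convergence:
restricted logL change < 1e-8 or parameter change < 1e-6 × var(y), max 100
iterations, non-convergence flagged rather than raised. Standard errors come
from the inverse AI matrix, ratio SEs by the delta method.

Single-kernel fits use a fast path: profile the restricted likelihood over
the ratio h² on the kernel eigenbasis and maximise by bounded Brent search.
The feasible upper bound for h² is reduced below 1 when the kernel has
negative eigenvalues, keeping V positive definite; this path is
algebraically the same optimum as the AI path, and the test suite asserts
agreement to 1e-6 in logL. Binary traits are analysed on the observed 0/1
scale (no liability transform). The LRT against the model without the tested
component uses the 50:50 chi2_0/chi2_1 boundary mixture, i.e. p is half the
chi-square-1 tail, and p = 0.5 at a zero statistic.

## Association

GWAS is the EMMAX approximation: variance components are fixed at the null
(no-SNP) REML fit, and each SNP is tested by GLS under
`V = sigma2_a G + sigma2_e I` on the eigenbasis of G. The Wald statistic
uses a Gaussian (chi-square-1) reference with the residual scale re-estimated
per SNP, so when sigma2_a → 0 the test is exactly OLS. Monomorphic SNPs get
missing p-values. Tiers label each SNP with the most stringent threshold it
passes among suggestive 1e-6, genome-wide 1e-8 and study-wide 0.05/N_SNPs.
mbGWAS runs one such scan per heritable feature (LRT p < 0.05), excluding
binary genera below 30% prevalence.

The MWAS regresses the covariate-adjusted phenotype (OLS residuals on the
factor dummies) on each genus — presence indicator below 60% prevalence,
CLR abundance at or above — with the top 3 genetic PCs as covariates, a
t reference with residual degrees of freedom, and Bonferroni correction over
all genera tested. The "top PCs" covariates here and in the heritability
scans are genetic PCs (the plausible reading; microbial PCoA scores are
separately available as community traits).

## Recursive scenarios

Marker genera are the Bonferroni-significant MWAS taxa; their mbGWAS hits at
the suggestive tier (configurable) form the indirect SNP set. Locus overlap
with the phenotype GWAS hit set uses exact SNP identity (a windowed overlap
is deliberately not the default). Each indirect SNP also receives a
Kruskal-Wallis test of the phenotype across its genotype classes
(tie-corrected H, chi-square reference); labels are non-exclusive:
"recursive (overlap)", "recursive (KW)" at p < 0.01, else "indirect only".

## Synthetic cohorts

The generator emulates the structure of a single-farm, single-breed cohort:

* genotypes: per-SNP allele frequency uniform on the MAF window
  (default 0.05–0.5), Hardy-Weinberg sampling, markers spread over 26
  autosomes, no linkage disequilibrium;
* microbiota: per-taxon latent Gaussian = standardized causal-SNP score
  (default 10 SNPs, equal variance shares, random signs) scaled by the
  taxon's h², plus noise; abundance = exp(baseline + latent), zeroed below
  the per-taxon quantile that hits the target prevalence, then closed to
  relative abundances. Default prevalence spectrum: ~4% of taxa at 100%,
  a high-prevalence block, and a long rare tail; default h² spectrum: ~40%
  of taxa heritable with h² uniform on 0.05–0.7, matching the share of
  genera found heritable in large ruminant cohorts. ~5% of taxa are labelled
  unclassified (and are removed by genus QC);
* phenotype: intercept 45 + evenly spaced covariate offsets (±0.5 SD over
  4 birthplaces and 2 seasons) + breeding value (default 500 causal SNPs)
  + microbial value (linear in z-scored taxa, so the MRM spans it exactly)
  + designed SNP effects + Gaussian residual, with variance fractions set by
  `pheno_h2`/`pheno_m2` (defaults 0.39/0.20);
* `to_counts` realises multinomial reads at ~35k depth when count data are
  needed (rarefaction, alpha diversity).

The exponential link with quantile truncation is a stand-in: the generative
distribution of real taxa is unknown, and any monotone positive link with
controlled zero-inflation would serve. Consequences worth knowing: CLR
abundances of a single taxon carry compositional leakage from its
neighbours, and zero-inflated neighbours inject pseudocount jumps into the
CLR row mean — so the measured-scale heritability of one taxon is attenuated
relative to its latent h². Passing tests therefore demonstrate estimator
correctness on this generative family, not that real rumen data meet its
assumptions (no LD, no pedigree, no batch structure, no phylogenetic
correlation among taxa).

A designed-truth configuration (`recursive_design_config`) plants two
full-prevalence marker genera (5% of phenotypic variance each), one
pleiotropic SNP (10% of marker-genus-1 latent variance + 5% direct
phenotype effect) and one taxon-only SNP (8% of marker-genus-2 latent
variance); `run_recursive_experiment` checks that the former is labelled
recursive and the latter indirect-only.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so the full
chain exercises every code path in minutes: variance-component recovery at
n = 800 with 5000 SNPs and 150 taxa (25 seeds in tests, 12 in the
acceptance script), LRT calibration with 200 null replicates at n = 300,
GWAS calibration at n = 500 with 2000 SNPs, recursive detection over 20
(tests) or 10 (script) designed cohorts at n = 800, and the pipeline demo at
n = 300. Mantel permutations default to 9999. All randomness flows from a
single seed through fixed per-stage child streams, so stages are
independently reproducible.

## Limitations

* The EMMAX approximation fixes variance components at the null fit; exact
  per-SNP REML is not implemented (standard practice for dense panels).
* Binary-trait heritability on the observed scale is not comparable across
  prevalences without a liability transform.
* The two-part MWAS is a linear probability model in its binary part.
* No mediation or Mendelian-randomisation machinery: "recursive" labels are
  overlap/association statements, not causal estimates.
* Ratio standard errors at a variance boundary (component fixed at 0) are
  reported as NaN; the LRT is the supported inference there.
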