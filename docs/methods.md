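# Methods

## The risk score

The score is a weighted allele count normalised by the total number of
possible alleles. Each locus carries weight `w = ln(OR)` when the tested
allele increases risk (OR > 1) and `w = ln(1/OR)` when it is protective
(OR < 1); in the protective case the *opposite* (non-protective) allele
is counted, so every locus contributes non-negatively and the score lives
on `[0, 2 Σw / 2L]`. With the default five-locus panel the maximum is
`2(ln 3.39 + ln(1/0.37) + ln 1.81 + ln(1/0.51) + ln 1.96)/10 =
0.8309396`. Loci with OR = 1 are rejected at model load: they carry zero
weight and no direction.

Missing genotypes have no published convention, so two policies are
implemented and recorded in the result: `strict` (default — any missing
locus is an error) and `rescale` (the denominator shrinks to twice the
number of observed loci, keeping scores on the same per-possible-allele
scale). Scores are carried at full double precision; rounding to two
decimals is display-only.

Because the loci are few, unlinked and modelled as independent, the exact
population distribution of the score under Hardy–Weinberg equilibrium is
enumerable (3^L = 243 genotype vectors). `exact_score_distribution` and
`exact_auc` (P(S₁>S₂) + ½P(S₁=S₂) by convolution) serve as closed-form
oracles for the sampling-based components; they are not used by the
scoring path itself.

## Genotype input and QC

VCF input goes through pysam; dosages count copies of the first ALT
allele, multi-allelic records are flagged and excluded rather than split.
Sequenced-data QC masks genotypes with GQ ≤ 20 or DP ≤ 10 and removes
variants with overall pass rate (OPR) ≤ 0.8; imputed-data QC removes
variants with call rate ≤ 0.95 or imputation Rsq ≤ 0.8. All thresholds
are strict inequalities, mirroring how they are conventionally printed,
and are overridable (CLI flags or a key=value config file). OPR is
treated as a supplied per-variant metric, not recomputed.

Harmonisation maps each model locus to a variant by rsID (an explicit
locus→variant mapping, e.g. from proxy selection, takes precedence).
Effect-allele dosage is the ALT dosage when effect = ALT and `2 − ALT`
when effect = REF; for non-ambiguous SNPs the complementary strand is
tried before giving up. Palindromic A/T and C/G sites cannot be oriented
from alleles alone and are rejected by default (`trust` accepts them
as-is for same-strand sources); silent mis-orientation would corrupt
scores, which is why rejection is the default. A second tabular input
dialect (sample_id + one counted-dosage column per rsID) covers cohorts
genotyped for only the five SNPs by targeted assays.

## LD proxies

r² is the squared Pearson correlation of unphased dosages (composite /
Rogers–Huff), phase-free and equal to the haplotype r² under HWE;
missing entries are pairwise-deleted and monomorphic input is an error
rather than r² = 0. An EM haplotype estimator would add phase information
but is unnecessary at these sample sizes and is left as an extension.
Proxy selection returns the index SNP itself when present; otherwise
candidates must exceed r² = 0.8 *strictly* and are ranked by quality
(imputation Rsq, else call rate), then r², then id — deterministic by
construction, with the substitution recorded in provenance. A proxy's
counted orientation follows the sign of its unsquared correlation with
the index effect allele.

## Kinship, unrelated set, ancestry

Kinship uses the heterozygote-concordance (between-family "robust")
estimator φ = (N_het,het − 2·N_opposing-hom) / (N_het(i) + N_het(j)) over
each pair's jointly observed markers. It needs no allele-frequency
estimates (robust to structure), gives exactly 0.5 for duplicate
genotypes, and is validated here by pedigree simulation (full sibs and
parent–offspring at 0.25) rather than formula transcription. The
unrelated set uses the common greedy surrogate for the NP-hard maximum
independent set: repeatedly drop the sample with the most above-threshold
partners (ties → higher missingness, then lexicographically larger id),
asserting on every run that no retained pair remains related; on small
clique-structured instances it matches exhaustive search to within one
sample. The default threshold 0.0442 is the conventional third-degree
cut; the relatedness cutoff, the number of PCs (default 10) and the
classifier family are not pinned down by any published choice and are
flagged as configurable assumptions.

PCA uses Patterson scaling (centre 2p̂, scale √(2p̂(1−p̂)), monomorphic
markers dropped) and stores loadings so study samples are projected onto
the reference space; missing study genotypes are mean-imputed after
centring. No shrinkage correction is applied to projections — a known
limitation that slightly contracts study scores toward the origin.
Classification fits a Gaussian class-conditional model with shared
covariance (linear discriminant) on the reference PC scores. A sample is
left unassigned when its maximum posterior is below 0.9 **or** when it is
atypical of the predicted class (Mahalanobis χ²(K) tail probability
below 1e-6 under the pooled within-class covariance). The typicality
guard exists because posteriors are purely relative: a sample far from
every centroid — admixed, or from an unrepresented population — would
otherwise saturate one class's posterior and be confidently mislabelled.
The floor 1e-6 is far below the typicality of genuine samples (empirically
≥ 1e-4 in the test panels) and far above that of cross-population
admixture, so it is insensitive to an order of magnitude either way.

## Cohort statistics

Summaries are medians with IQR using linear-interpolation (type-7)
quantiles. Group comparisons use the Kruskal–Wallis rank test with tie
correction (χ² reference, k−1 df); all-identical input degenerates to
p = 1 with a warning. Planned comparisons are two-group rank tests of
each cohort against the control at a Bonferroni-divided threshold —
seven comparisons give 0.05/7 ≈ 0.00714, conventionally displayed 0.007.
The seven groups compared against healthy controls are SSNS, MCD, SRNS
(primary), SRNS (delayed), FSGS, monogenic and MN, which is what makes
the divisor seven; all-pairs comparisons among the INS groups are
available separately.

The ROC is empirical over all observed thresholds with "score ≥ t ⇒
predicted non-monogenic" orientation; trapezoidal AUC equals the
tie-corrected pairwise concordance exactly (asserted in tests against an
all-pairs brute force). The optimal cutoff maximises Youden's J, ties
broken toward the lower threshold; "closest to (0,1)" is available by
flag since the published cutoff-selection wording admits either reading.
The CI is DeLong by default (no installed package provides it, so the
midrank placement-variance form is implemented here and its ~95%
coverage is verified by simulation); a seeded stratified bootstrap is
the alternative.

## Synthetic data

The generator emulates the study conditions rather than any real
population. Unaffected cohorts draw counted genotypes per locus from HWE
at baseline frequencies; affected cohorts reweight genotype probabilities
by OR^g per counted allele (the rare-disease multiplicative model), which
is equivalent to HWE at the shifted frequency p′ = p·OR/(1−p+p·OR) — the
closed form the tests check against. An exact (non-rare) logistic
sampler behind a prevalence parameter (default 0.001) is provided and
agrees with the approximation at that prevalence. Monogenic-like and
membranous-nephropathy cohorts are drawn from the *unaffected*
distribution: this encodes the observed finding (their score is not
elevated) without assuming a mechanism. The five loci are simulated
without LD (they lie in distinct regions) and, within the HLA, the
independence assumption is a simplification real data would violate.

Baseline counted-allele frequencies default to (0.30, 0.40, 0.35, 0.45,
0.20) — plausible common-variant values chosen once for realism and
labelled illustrative; the real per-cohort frequencies are unpublished,
so absolute medians/AUC of the synthetic study are not, and are not
claimed to be, numeric reproductions. Passing tests therefore demonstrate
correctness of the machinery and the *direction* of every cohort-level
finding, not the published point estimates.

Marker panels for kinship/ancestry testing use Balding–Nichols
divergence: each population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F)
around a shared ancestral p ~ U(0.1, 0.9), so F equals the expected
Hudson-style FST (verified in tests at F = 0.1 ± 0.02). Pedigree blocks
drop gametes from two founders to produce parent–offspring and full-sib
pairs with recorded truth; missingness is uniform at random. Every
artefact is a pure function of (spec, seed).

`emulate_paper_cohorts` assembles the full study at the published sizes
(88 + 139 + 280 + 41 + 49 + 1108 + 5642 = 7347 samples). The cohort map
carries seven cohort labels plus a subtype column splitting SRNS into
primary (121) and delayed (159), which the planned comparisons use.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately desk-scale sizes chosen as the
package's own defaults: 10⁵ draws for distribution-convergence checks
(KS < 0.01), 20 000 markers for kinship recovery (sib φ within ±0.02),
10 000 markers / 5 populations / 100 reference samples per population
for ancestry (accuracy ≥ 99 %), 1 000 replicates for type-I-error
calibration (0.05 ± 0.015), 200 replicates for power and OR-recovery
properties. Score probabilities in the exact distribution are merged at
1e-12; kinship denominators of zero (no shared heterozygotes) yield
φ = 0; PCA rank is checked against a 1e-10 relative singular-value
floor. Degenerate inputs (constant cohorts, empty study sets,
monomorphic variants) return defined results or typed errors, never
silent NaNs.

## Known limitations

* No genotype imputation, phasing, BGEN/PLINK-BED input, or EM haplotype
  LD; no covariate-adjusted or survival modelling.
* Projection shrinkage is uncorrected; with few reference samples and
  many PCs the typicality guard may become conservative.
* The greedy unrelated set is a heuristic; it is exact only on the small
  structured instances tested.
* Synthetic cohorts share one baseline frequency vector across cohorts
  and populations; real cohorts differ by ancestry and genotyping
  platform in ways the generator does not emulate (batch effects,
  differential missingness, LD between HLA loci).
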