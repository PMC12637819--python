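# Methods

## The interaction model and its estimands

The pipeline detects cis genetic effects on CpG methylation that depend on
a tissue's cell-type composition. For individual *i* the transformed
methylation level is modeled as

    y_i = b0 + b1 G_i + b2 C_i + b3 G_i*C_i + b4 Age_i + b5 Sex_i
          + sum_k gamma_k PCgen_ik + sum_l delta_l PCdnam_il + e_i

with G the alt-allele dosage (0/1/2) of a variant within +/-500 kb of the
CpG and C the rank-based inverse-normal transform (INT) of the estimated
proportion of one cell type. The response is the INT of the M-value
(log2 beta/(1-beta)) computed per CpG across samples. Three genotype
coefficients matter downstream:

- the **interaction** b3 (the imQTL effect): how the allelic effect scales
  with the cell type's abundance;
- the **main effect** b1 from the same model;
- the **marginal effect**: the genotype coefficient of the model with the
  C and G*C terms removed — the bulk-tissue mQTL effect. We fit the
  marginal model cell-agnostically (no proportion term at all), because
  it represents the conventional mQTL scan used as the comparison point;
  the proportion main effect belongs to the interaction model only.

The interaction regressor is G times INT(C) — the raw dosage multiplied
by the transformed proportion — not an INT of the product; the transform
is a property of the proportion, the product is formed afterwards.
P-values come from the t distribution with df = n minus the number of
fitted coefficients, which matters at the sample sizes (tens to a few
hundred) typical of tissue DNAm studies.

All scans run through one vectorized least-squares engine that assembles
per-CpG stacked normal equations (covariate block shared, genotype and
interaction columns varying per variant), with non-intercept columns
centered for conditioning — a reparametrization that leaves every
reported coefficient and standard error identical to per-pair OLS. The
test suite holds the engine to 1e-8 relative agreement with an
independent `lstsq` oracle on 1,000 random pairs; in practice agreement
is ~1e-13.

### Filters and multiple testing

Variants enter an interaction scan only if their MAF exceeds 0.1 in both
halves of the modeled cell type's proportion distribution (split at the
median, ties to the lower half). This guards against interaction
artifacts from alleles private to one composition stratum. Marginal scans
use the plain MAF > 0.1 cutoff. Variant QC upstream drops variants with
any missingness, Hardy-Weinberg exact-test p < 1e-6 (exact enumeration of
the heterozygote-count distribution, no mid-p), or MAF <= 0.1.

Per CpG, the minimum interaction p-value is multiplied by an effective
number of independent tests M_eff: the smallest count of leading
eigenvalues of the cis-variant correlation matrix capturing >= 99.5% of
its trace. M perfectly correlated variants give M_eff = 1 (no penalty);
independent variants give M_eff close to M. The EMT-adjusted p-values are
then Bonferroni-corrected across tested CpGs; a CpG's lead pair (smallest
p, ties broken by distance then variant id, so leads are deterministic)
is a significant imQTL iff the final p < 0.05. The arithmetic guarantees
p_final >= p_EMT >= p_min.

Secondary signals: every variant within +/-500 kb of a lead is refitted
with the lead's genotype and interaction as extra covariates; conditional
interaction p < 1e-5 flags a candidate (perfect proxies of the lead are
skipped). Pleiotropy is the count of distinct CpGs with interaction
p < 1e-4 for a lead variant.

## Deconvolution

The reference panel is built from sorted-cell beta matrices by
one-vs-rest differential methylation per cell type with an
empirical-Bayes moderated t-test (per-CpG pooled variances shrunk toward
a scaled inverse-chi-square prior fitted by moment matching on log
variances; verified against Bioconductor limma to ~1e-13 on both the
finite and infinite prior-df branches). A CpG becomes a DMC for a type
when (i) BH-FDR < 0.001, (ii) it is hypomethylated in that type versus
the pooled rest — highly cell-type-specific CpGs are unmethylated in
their type — and (iii) the absolute mean-beta difference exceeds the
type's threshold (0.9 immune, 0.8 epithelial, 0.81 fibroblast, 0.715
endothelial; 0.7 floor for unnamed types), large enough that batch or
technical effects (< 0.2) cannot produce it. "Versus the rest" is the
pooled mean of the other types, not each pairwise comparison (a pairwise
mode would be stricter; the pooled form matches the single difference
per comparison used to set the thresholds). A CpG passing for two types
is assigned to the type with the larger difference so each DMC has
exactly one target. The centroid is the per-type mean beta over the
selected DMCs.

Proportions are estimated per bulk sample by RPC (robust partial
correlation): Huber-loss IRLS regression (tuning constant 1.345,
convergence 1e-8, at most 500 iterations, via statsmodels RLM) of the
sample's beta values at panel DMCs on the centroid columns, without an
intercept — under simplex mixing the centroid columns span the constant.
Negative coefficients are truncated to zero and the rest renormalized to
sum to one, so estimates live on the probability simplex and minor cell
types produce exact zeros, as observed in practice. Cell types whose
estimated proportion is exactly zero in more than half of individuals
(strict >) are excluded from mapping.

Panel validation generates 500 in-silico mixtures: one held-out profile
per cell type, flat-Dirichlet weights (the maximum-entropy choice for
random weights that add to one), optional Gaussian noise; agreement is
summarized by Pearson r and RMSE per cell type. With the default
synthetic panel and noise SD 0.05, r exceeds 0.999 per type.

## Downstream classification

**Directional consistency.** An imQTL is `unknown` when its marginal
p-value exceeds 1e-5; otherwise `consistent` iff the marginal effect and
interaction term share a sign. The percentage consistent is reported over
all imQTLs of a cell type.

**Cell-type specificity** uses two criteria: (1) the modeled type's
interaction has the opposite sign to every other type's, or no other type
reaches nominal significance (p < 0.05); and (2) the genotype-methylation
association is nominally significant among individuals in the modeled
type's upper proportion half, while every other type's upper-half
association is either non-significant or oppositely directed.
"Individuals enriched for other cell types" is operationalized as each
other type's own upper-50% subset — the only split the procedure defines.

**Effect sharing.** Entry (a, b) of the sharing matrix (rows the
reference type a) is the fraction of the tissue's imQTLs — the union of
lead pairs across cell types — for which type b's interaction has the
same sign as a's and b's p < 0.05, over pairs testable in both (pairs
untestable in b are excluded and logged). The matrix is not symmetric;
display order comes from average-linkage clustering of one minus the
symmetrized sharing.

**Replication** validates a discovery imQTL when the replication
interaction p < 0.05 with matching sign after allele harmonization
(match on chrom/pos; ref/alt swap flips the sign; strand flips are
refused rather than guessed).

## Enrichment and colocalization

Annotation enrichment compares QTL features (lead variants against the
background of all tested cis variants; CpGs against all array CpGs) by a
two-sided Fisher exact test on the 2x2 in/out-annotation by
target/rest table. Log odds ratios use the Haldane-Anscombe 0.5
correction when any cell is empty, with Woolf standard errors
sqrt(1/a+1/b+1/c+1/d) — the standard choice when only the table is
available. Interval membership is 0-based half-open (a feature at
`start` is inside, at `end` outside); variant and CpG positions arrive
1-based and are shifted once, so results are invariant to splitting an
interval into abutting pieces. Per-tissue log odds ratios are pooled by
DerSimonian-Laird random effects: tau^2 = max(0, (Q - df)/C), weights
1/(SE^2 + tau^2) (implemented directly because the statsmodels DL path
does not truncate tau^2 at zero; cross-checked against statsmodels where
the truncation is inactive).

Cell-type EWAS regresses each CpG's transformed methylation on a cell
type's proportion plus covariates; differentially methylated sites (DMS)
pass BH-FDR < 0.05 (the threshold is exposed — no canonical value
exists).

Colocalization assumes at most one causal variant per trait per locus.
Each variant's Wakefield log approximate Bayes factor is
0.5 log(V/(V+W)) + 0.5 z^2 W/(V+W) with V the squared SE and sqrt(W) =
0.15 for quantitative traits (0.2 for case-control). Hypothesis weights
H0=1, H1 = p1 S1, H2 = p2 S2, H3 = p1 p2 (S1 S2 - S12), H4 = p12 S12
(S1, S2, S12 the ABF sums and cross-sum) are normalized into PP0-PP4;
all sums run in log space with log-sum-exp because ABFs overflow doubles
beyond |z| ~ 40. Default priors are (1e-4, 1e-4, 1e-5); biologically
informed priors derive from genome-wide counts as p1=(n1-s)/N,
p2=(n2-s)/N, p12=s/N. A locus colocalizes when PP4 > 0.5 (strict); per
CpG the partner with the highest PP4 is the top colocalization. The
enumeration is held to 1e-10 agreement with brute-force enumeration over
all causal-configuration pairs on loci of up to 6 variants.

## The synthetic-data generator

Bulk methylation is generated exactly under the mixture model the
analysis assumes: beta_ij = sum_k pi_ik (m_jk + b_jk g_i) + eps_ij,
clipped to [1e-3, 1 - 1e-3] so M-values stay finite. Defaults, chosen
once as plausible for EPIC-array tissue data:

- `noise_sd = 0.05` beta-scale measurement noise (the residual magnitude
  of bulk DNAm is not established; this is a free parameter).
- Per-CpG baselines uniform on (0.1, 0.9) with per-cell-type deviations
  of SD 0.1 (`celltype_baseline_sd`) — distinct cell-type methylomes are
  the premise of deconvolution.
- Covariates age ~ N(50, 10), sex ~ Bernoulli(0.5), not affecting
  methylation unless confounding is switched on, so covariate plumbing is
  exercised without biasing recovery tests.
- A single global seed fans out to per-operation child seeds, making full
  studies bit-reproducible while individual generators can be re-run.

Sorted-cell reference data place planted DMCs at (1-delta)/2 in the
target type and (1+delta)/2 elsewhere; summary-statistic pairs regress
two simulated traits (no, shared, or distinct causal variants, effect
scaled to a target z) on fresh genotype panels, with optional first-order
LD. What the generator does **not** emulate: realistic LD beyond that
single knob, probe chemistry and array normalization artifacts,
non-MCAR missingness, and genetic population structure — so passing
tests demonstrate correctness of the statistical machinery under the
model's assumptions, not robustness to every failure mode of real data.

## Reference experiments and their problem sizes

- **Sign recovery / specificity** (200 replicates, n = 2,000, planted
  beta 0.2): the modeled cell type is a rare, highly dispersed type
  against a dominant background (Dirichlet (0.1, 1.0)) — the setting in
  which candidate cell-type-specific effects arise in practice, since the
  two-part rule can only hold when the modeled type is near-absent in
  individuals enriched for other types. Observed: 100% sign recovery,
  ~95% clean specificity calls (failures are the rule's own nominal-alpha
  false positives in null strata).
- **FWER calibration** (200 null studies, n = 200, 50 CpGs x 20 cis
  variants): runs under shared baselines across cell types. With
  strongly cell-type-divergent baselines the INT response's residual
  variance depends on the proportion, and the OLS interaction test shows
  mild tail inflation (p < 1e-4 at ~2-3x nominal) — a known
  heteroscedasticity effect of interaction tests, shared by any OLS-based
  implementation of this model and worth remembering when interpreting
  borderline imQTLs at strongly composition-driven CpGs. Under the
  model-consistent null the pipeline is calibrated (interaction p-values
  KS-uniform; FWER ~0.03-0.05 against the 0.081 acceptance bound).
- **Power vs proportion variance** (200 replicates per setting, n = 300,
  effect 0.15, mean proportion fixed at 0.3): Dirichlet concentrations
  40 / 8 / 1.5 give proportion variances 0.005 / 0.023 / 0.084 and
  powers ~0.5 / ~0.99 / ~1.0 — detection power rises with
  inter-individual proportion variance, the composition property the
  interaction design exploits.
- **Deconvolution recovery** (500 mixtures, noise SD 0.05): panel built
  from 12 sorted samples per type with planted DMC counts 62 / 65 / 60 /
  66 (the generic four-cell-type panel's composition, 253 DMCs total)
  plus sub-threshold decoys; held-out samples form the mixtures.
- **Colocalization calibration** (100 replicates): shared causal variant
  at z ~ 8 in both traits gives PP4 > 0.9 in ~100% of replicates; null
  loci at small n rank PP0 first in ~100%.

## Numerical choices and degenerate inputs

- INT uses offset (rank - 0.5)/n with average ranks on ties; constant
  vectors are rejected (ranks carry no information for QTL use).
- kNN imputation (k = 10) operates on CpG rows — neighbouring probes are
  the informative axis — via scikit-learn's KNNImputer (uniform weights;
  its nan-Euclidean distance is the shared-column Euclidean rescaled by
  completeness, which preserves the zero-distance-duplicate and
  neighbourhood semantics).
- PCA is SVD on centered (and for genotypes, variance-standardized)
  data; each component's largest-magnitude loading is made positive so
  scores are reproducible across runs and sample orderings. Genetic PCs
  use greedy LD pruning (r^2 <= 0.2 within 500 kb, position order).
- The number of methylation PCs comes from a scree elbow. The classic
  chord (distance-to-line) rule was implemented and evaluated first: on
  planted-factor data it lands one past the factor count and on pure
  noise it lands deep inside the eigenvalue bulk (L ~ 30), because a
  smooth Marchenko-Pastur scree has no corner. The default is therefore
  the largest spectral gap, guarded by a dominance check (max gap >= 10x
  the median gap, else a single component): planted factor counts are
  recovered and structureless data yield L = 1. The chord rule remains
  available via `method="distance"`.
- Rank-deficient designs are dropped from scans with a logged reason;
  zero-variance covariate columns are removed up front; all-equal scree
  curves select one component with a warning; empty QC results warn
  rather than raise.
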