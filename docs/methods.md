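# Methods

This note records the statistical models, the synthetic-data generator's
scope, and the numerical choices made where the design was genuinely
open. It documents what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## The quantitative-genetic model

Each ASV's spatially corrected abundance is modelled as
`y = Xb + Za ua + Zf uf + Zc uc + e` with `ua ~ N(0, A σa²)`,
`uf ~ N(0, I σf²)`, `uc ~ N(0, I σc²)`, `e ~ N(0, I σe²)`. The design
rests on two kinds of replication. Full-sib families plus a
multi-generation pedigree identify the additive component through the
relationship matrix `A`; clonal ramets replicate whole genotypes, so a
genotype-level component with identity covariance (`uc`) is separable
from the residual. Classical full-sib covariance theory
(`Cov(FS) = ½VA + ¼VD`) implies the family component absorbs one quarter
of dominance variance, while the clone component carries the remaining
three quarters of dominance plus all epistatic variance. The package's
gene-dropping machinery reproduces this 25/75 partition empirically
(`scripts/acceptance.py`), which is the design-based justification for
interpreting `σf²` and `σc²` as non-additive variance.

Broad- and narrow-sense heritability are `H² = (σa²+σf²+σc²)/σ_total²`
and `h² = σa²/σ_total²`. Standard errors come from the first-order delta
method using the inverse average-information matrix; z = estimate/SE,
significant when |z| > 1.65 (the one-sided normal threshold at α = 0.05;
Φ⁻¹(0.95) = 1.6449, quoted at the conventional two-decimal table value).

### REML implementation

The optimiser takes average-information (AI) steps with step-halving and
an EM-style fallback whenever an AI proposal is not an ascent step.
Components are constrained to ≥ 1e-8 × the phenotypic variance; an
active set pins a component at that floor while its score points
outward and releases it when the score turns inward (without this,
boundary fits oscillate). Convergence requires a relative log-likelihood
change below 1e-8 (default cap 100 iterations); non-convergence is
flagged on the result, never raised. SEs for pinned components come from
the information matrix projected onto the free components, and a
heritability ratio whose numerator consists only of pinned components is
never called significant — its projected SE is a boundary artifact, and
without this guard a null scan produces spurious z > 1.65 calls at far
above the nominal rate.

Estimator properties verified in the suite: exact agreement with the
closed-form balanced clonal ANOVA estimator (relative difference ~1e-13);
delta-method SEs within 25% of parametric-bootstrap SDs; scale/shift
equivariance; and mean component estimates within Monte-Carlo error of
truth over 200 replicates at the full design size (132 genotypes × 4
ramets), where mean H² at truth 0.6 is recovered within 0.03. Small
truncation biases from the positivity constraint (order ±0.02 on
individual components at this design size) are inherent to bounded REML
and visible in the recovery test's tolerances.

## Spatial correction

Micro-site gradients create smooth spatial trends in abundance that
would otherwise masquerade as genetic signal. Each ASV's square-root
counts are detrended with a penalised thin-plate spline over the
planting coordinates (kernel `r² log r` plus an affine null space). The
reduced form — eigendecomposition of the penalty projected onto the
affine complement — is computed once per coordinate set and shared
across ASVs, making each (ASV, λ) evaluation O(n²). λ is selected per
ASV by generalised cross-validation over a 61-point log grid spanning
interpolation to near-affine fits; a fixed λ can be supplied instead
(0 = exact interpolation). Duplicate coordinates are collapsed by
averaging with a warning; collinear coordinates are an error.

Two residual variants are produced, matching their different consumers:
unadjusted residuals (which retain negative values) feed the mixed
model, while a per-ASV rigid shift to a zero minimum produces the
non-negative inputs Bray-Curtis requires. The shift preserves all
pairwise differences; "non-zero adjustment" is implemented as
non-negativity with minimum exactly 0, since residuals from a model
with an intercept almost surely have a negative minimum and the purpose
of the adjustment is a valid dissimilarity input.

Known limitation: the two-stage pipeline (GCV spline, then REML treating
residuals as data) carries a small downward H² bias because a fraction
of the genetic signal lies in the smooth subspace the spline removes and
the unremoved sliver of trend inflates σe². At the generator's default
trend smoothness (≤ ~¾ cycle across the trial) the spline removes ≥ 97%
of a 30%-share spatial component and the measured bias is about −0.01
at H² = 0.6; rougher trends (several cycles across the trial) increase
the bias to about −0.03 even though ~97% of the trend is still removed.
Practitioners with strong fine-scale spatial structure should interpret
per-ASV H² as slightly conservative.

## Community analyses

Bray-Curtis dissimilarities are computed on the adjusted residuals
(all-zero row pairs get distance 0 and are flagged). PERMDISP embeds the
distance matrix by principal coordinates with the negative-eigenvalue
correction (squared centroid distance = real-part minus imaginary-part,
clipped at zero), takes the classical one-way F on centroid distances,
and permutes group labels.

The nested PERMANOVA uses the Gower identity: `G = -½ C D² C` has
`tr(HG)` equal to the sum of squares for the design subspace with
projection `H`. Terms are fitted sequentially (Type I), each term's SS
being the trace against the difference of cumulative projections built
by SVD (rank-deficient additions are reported as aliasing errors).
Choices that the distance-based ANOVA literature leaves open:

* **Denominators.** A random term is tested against the next random term
  nested inside it (family over genotype-within-family); the deepest
  random term and the leading fixed covariates are tested against the
  residual mean square.
* **Components of variation.** Moment equations
  `E[SS_j] = Σ_r σr² tr(P_j Zr Zr') + df_j σe²` are solved bottom-up;
  the projections make the system triangular, and for balanced designs
  the estimates coincide exactly with the classical nested-ANOVA moment
  estimators (verified in the suite). Negative components are retained
  and reported as signed square roots (`sign(CV)·√|CV|`), so a negative
  genotype component prints as a negative `√CV`. Fixed-term components
  use the same moment equation applied to the term's own indicator
  matrix — an effect-size analogue, not a variance.
* **Permutation scheme.** p-values permute the residuals of the reduced
  model containing all prior terms (`(count ≥ observed + 1)/(n_perm+1)`,
  with a relative tolerance so tied statistics stay in the count). The
  exchangeable units depend on the term: for a random term tested
  against a nested random denominator, whole denominator groups are
  permuted as blocks when their sizes are equal (the exchangeable units
  under that null); free permutation of sample residuals — which is
  what unbalanced group sizes fall back to — makes that test measurably
  conservative when the nested term carries variance (empirical type-I
  0.02 vs block-permutation 0.04–0.05 at nominal 0.05 in the suite's
  calibration experiment).

## The synthetic-data generator

The generator emulates the target trial design end to end: a
three-generation pedigree whose final generation is 28 full-sib families
of 3–6 genotypes (132 total, shared parents allowed, so half-sib links
arise); a single-tree incomplete-block layout of 4 ramets per genotype
(528 trees) on contiguous ~36-tree blocks with each genotype at most
once per block; soil covariates drawn multivariate-Gaussian at the
calibrated means/SDs (pH 4.63 ± 0.18; moisture 43.9 ± 6.0%; total C
9.79 ± 2.46%; total N 0.45 ± 0.10%) and correlations (pH–C −0.78, pH–N
−0.70, C–N 0.89; the unreported moisture correlations default to −0.3
with pH and +0.3 with C and N — arbitrary values chosen to keep the
matrix positive definite, which it is without repair); genetic values by
Mendelian gene dropping at independent biallelic loci with additive
effects `a(dose − 2p)`, dominance deviations `d(het − 2p(1−p))`, and
optional additive×additive epistasis on random locus pairs; and counts
drawn compositionally — per-sample expected depth (default 10,000 reads
× a lognormal library-size factor) allocated across ASVs by softmax of
the latent log-abundances, then negative-binomial (Poisson at
overdispersion 0). A quarter of ASVs get high "core" baselines
calibrated to ≥ 80% prevalence at default depth; 30% of ASVs receive a
genetic slope (SD 0.35 on the latent scale), which yields the
low-to-moderate heritability world such studies report — mostly
negligible H² with a tail reaching ~0.4–0.6. Spatial trends are sums of
three sinusoidal plane waves at ≤ ~¾ cycle across the trial extent;
sequencing batches (two by default) are assigned by contiguous layout
regions, mimicking plate structure. A master seed spawns independent
child streams per stage, so the whole bundle is bit-reproducible and
stages can be regenerated independently.

What the generator does **not** emulate: taxonomy (no chloroplast/
mitochondria filtering semantics), read-level artefacts (chimeras,
primer issues), zero-inflation beyond what the negative binomial
produces, temporal structure, and genotype-by-environment interaction.
Passing tests therefore demonstrate correctness of the estimators under
the declared generative model, not robustness to every feature of real
amplicon data.

## The dominance-partition experiment

The calibration experiment drops 2,000 pure-dominance loci (allele
frequency 0.5, zero additive effects) through 200 independent full-sib
families of 50 progeny and partitions the variance of genetic values
between and within families. The partition is estimated per locus with
the balanced one-way ANOVA moment estimators and pooled across loci
using squared dominance effects as weights: loci are independent, so
the cross-locus covariance terms this drops have zero expectation, and
pooling shrinks the Monte-Carlo SE from ~1.9 percentage points (the
resolution of the aggregate estimator, dominated by the 200 family
draws) to ~0.25. Observed values sit at 24.8–25.0% between families and
75.0–75.2% within, against the theoretical 25/75.

## Numerical conventions

* Rarefaction is a single multivariate-hypergeometric draw per sample at
  a recorded seed; samples below depth are dropped and reported.
* Soil PC1 uses mean imputation, z-scoring, and the correlation-matrix
  eigendecomposition; the sign is fixed so pH loads positively;
  zero-variance columns are an error naming the column.
* Core membership is computed on the rarefied table (after low-depth
  samples are dropped).
* Unknown parents are unique unrelated non-inbred founders; `A` is built
  over the whole pedigree and subset to sampled genotypes.
* The per-ASV scan records failures and non-convergence per ASV and
  never aborts; batch enters the fixed effects with first-level
  reference coding; no multiple-testing correction is applied to the
  headline significance counts (a per-ASV α, matching the analysis this
  package implements), though the results table carries everything
  needed to add one.

## Problem sizes in the test suite

Simulation-based checks run at the sizes their precision requires while
keeping the suite fast: parameter recovery at the full design
(132 × 4, 200 replicates), spline recovery over 100 ASVs at the full
layout, PERMANOVA type-I calibration on 200 null datasets of a reduced
20-family design with 199 permutations, the bootstrap-SE comparison at
200 refits, and the relationship-matrix oracle at 1e5 gene-dropping
replicates on a 50-individual pedigree.
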