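# Methods

This note documents the models behind `admixgs`, the choices made where
the design was genuinely open, and what the synthetic data can and cannot
show.

## Population model

Founders are drawn from `n_subpops` wild subpopulations under the
Balding–Nichols construction: per marker an ancestral frequency p is drawn
uniformly on `ancestral_freq_range`, and each subpopulation's frequency is
Beta((1−F)/F·p, (1−F)/F·(1−p)) with F = `divergence`. A single parameter
thus controls the between-subpopulation frequency variance F·p(1−p) that
generates admixture LD; F = 0.15 (default) produces frequency deviations
typical of moderately diverged river strains. Founder haplotypes are drawn
in linkage equilibrium within subpopulation — real wild populations carry
short-range LD, so simulated founders understate within-population LD; the
admixture-generated LD structure (the object of study) is unaffected.

Meiosis is Haldane: crossover counts per chromosome are Poisson with mean
equal to map length in Morgans and breakpoints are uniform; there is no
interference, no mutation, and no sex-specific map. Generation 1 is the
admixed F1 (each parent's subpopulation sampled by the contribution
vector); later generations mate within the closed line, by default in a
partial-factorial design mirroring a commercial year-class
(157 families from 99 dams and 97 sires at full scale). Every allele
carries a *descent label* identifying the founder gamete it was copied
from, so realized IBD is known exactly — the reference for validating the
linkage-analysis estimator. Reduced designs used in tests are stated with
each result (typically 40–80 families, 2–5 chromosomes); the package-level
defaults in `ScenarioConfig` (5 chromosomes × 240 markers, 80 families ×
12 offspring ≈ 960 evaluated fish, 3 generations) are the desk-scale
study conditions for the model-comparison experiment.

There is no selection-on-EBV feedback across generations; selective
genotyping of extreme families is available as a sampling step
(`select_genotyped`), not as a change to the breeding history.

## Traits

QTL positions are sampled from the mapped markers; additive effects are
Gaussian (or uniform). Effects are rescaled once so that the realized
genetic variance among base-generation individuals equals exactly
h²·`phen_var`; the residual variance is (1−h²)·`phen_var`. For a pair of
traits the second effect vector is re-expressed as a linear combination of
the two raw vectors so the base-generation TBV correlation is exactly the
target (a linear combination of genic values is itself a genic value).
Defaults follow the two study traits: lice resistance h² = 0.14 on the
log-density scale with phenotypic variance 0.53, fillet colour h² = 0.43
with variance 0.96, genetic correlation 0.72 between repeated lice tests.

The count trait is generated on the latent log-lice-density scale
(LogLD = μ + fixed + a + e, default μ = −1.7), body weight is lognormal
(defaults 800 g mean, 290 g SD), and the integer count is recovered as
max(0, round(exp(LogLD)·BW^(2/3) − 1)) — the inverse of the forward
definition LogLD = ln((LC+1)/BW^(2/3)), rounded and clipped so zero counts
occur. This reproduces the skewed count distribution while the recomputed
LogLD stays normal up to rounding (error < 1/(LC+1) per fish). Fixed
effects are test, person-by-day within test, and gender; their magnitudes
(SDs 0.3 / 0.25, gender shift 0.2) are nuisance-scale choices, removed as
fixed effects in analysis.

## Relationship matrices

*Pedigree A*: tabular method, a_ii = 1 + F_i, parents topologically
sorted first (Kahn, FIFO, stable for already-sorted pedigrees).

*Genomic G*: VanRaden's second method — each marker centred at 2p and
standardised by its own variance 2p(1−p) before averaging, p from the
observed genotyped sample by default (base-generation frequencies can be
supplied; sample frequencies carry the usual −1/N centring bias, which the
ADJUST step absorbs). Monomorphic markers are dropped. A GRM built from
fewer markers than individuals is rank-deficient; downstream code detects
this (Cholesky) and never inverts it.

*ADJUST*: the two-moment affine rescale G* = α + βG solving
mean diag(G*) = mean diag(A22) and mean offdiag(G*) = mean offdiag(A22).
This is the implemented definition of putting G on the pedigree base; it
is applied to both the GRM and the IBD matrix before any single-step
combination.

*Single-step H*: the standard construction, dense via the block identity
(H22 = G, H12 = A12·A22⁻¹·G, …) and the inverse via
H⁻¹ = A⁻¹ + [[0,0],[0,G⁻¹−A22⁻¹]]. Optional blending
G ← 0.95 G + 0.05 A22 guards singular G (off by default).

### Linkage-analysis IBD

The IBD module estimates *realized* relationships by tracing transmitted
chromosome segments, conditioned on the recorded pedigree with founders
assumed pairwise non-IBD. Per chromosome:

1. **Transmitted alleles.** For each offspring × parent × marker the
   transmitted allele is resolved by genotype arithmetic where
   unambiguous (a 4×4×4 lookup over offspring/parent/other-parent
   genotype, missing allowed).
2. **Family phasing.** Each parent's haplotypes are reconstructed from
   those transmissions: heterozygous markers are linked through each
   offspring's consecutive *informative* markers (a link vote is wrong
   only if that offspring recombined in between) and resolved by
   sequential majority. For a non-founder parent, the alleles it received
   from its own sire are hard anchors: haplotype 0 *is* the sire gamete
   there, so chain errors cannot propagate past an anchor and the
   orientation to the grandparents is fixed. Founder parents get an
   arbitrary per-chromosome orientation, which is harmless because their
   two gametes are exchangeable non-IBD labels.
3. **Transmission HMM.** A two-state chain per offspring × parent over
   the chromosome's markers: transitions are Haldane recombination
   fractions between adjacent markers; emissions score the transmitted
   allele against the phased parental haplotypes with a small mismatch
   probability ε = 0.01 absorbing residual phasing errors; uninformative
   markers are flat. Forward–backward yields the posterior probability
   that the grandpaternal haplotype was transmitted at each locus.
4. **Gametic recursion.** At an evenly spaced grid of marker loci
   (default 24 per chromosome; the acceptance runs state their grid) the
   gametic relationship matrix is filled down the pedigree: an offspring
   gamete's IBD row is the posterior-weighted mixture of its parent's two
   gamete rows. Locus matrices are averaged within chromosomes and
   chromosomes averaged with equal weights (length-weighting available).
   The result is on the additive scale: non-inbred diagonal 1 and
   parent–offspring exactly 0.5 irrespective of markers (a whole gamete
   is transmitted, so the posterior cancels).

With no marker information every posterior is ½ and the recursion returns
the pedigree A exactly — the estimator degrades gracefully to the prior.
Accuracy is validated against the simulator's descent labels (RMSE ≈
0.002–0.005 under dense informative markers), not against any external
phasing software; the method is a linkage-only analysis and does not use
population LD, so ungenotyped parents of genotyped fish reduce it to
pedigree expectations for the affected links. The experiment driver
therefore genotypes the ancestors of the evaluated generation.

## Mixed models

BLUP solves Henderson's equations at fixed variance components; when the
relationship matrix is not positive definite the mathematically equivalent
GLS route is used (β̂ = (X'V⁻¹X)⁻X'V⁻¹y, â = σ_g²·G·Z'V⁻¹(y − Xβ̂) with
V = σ_g²·Z G Z' + σ_e²·I), which never inverts G. Confounded fixed effects
fall back to a minimum-norm generalized inverse with a warning; only
estimable functions are then meaningful.

REML maximises the restricted likelihood with average-information steps,
step-halving until the likelihood does not decrease (so the accepted
trajectory is monotone), variances floored at 1e-10 × phenotypic variance
(a floored estimate is flagged as a boundary), convergence at relative
parameter change < 1e-8, at most 200 iterations. The univariate
single-component model uses a one-off eigendecomposition of Z G Z' making
each iteration O(n); multi-component models (common-environment family
effect) and the bivariate model (genetic structure A ⊗ G0, trait-specific
residuals, zero residual covariance, G0 kept PSD by eigenvalue clipping)
use the dense engine. Standard errors come from the inverse AI matrix;
h² and r_g SEs by the delta method. Likelihood-ratio tests for a single
variance component use the 50:50 χ²₀/χ²₁ boundary mixture.

## Evaluation

Cross-validation follows the masked-phenotype protocol: the
genotyped-and-phenotyped set is split into k = 5 random folds (sizes
within 1); each fold's phenotypes are removed, the model refit on the
rest with variance components fixed (estimated once from all data with
the pedigree model — the identical-variance-components convention), and
the validation EBVs recorded. Reliability is r²(EBV, y)/h², reported
pooled over folds (default estimand) and as the per-fold mean with its
Monte-Carlo SE; finite-sample values above 1 are reported as-is with a
warning. Gains are 100·(model/PED − 1) percent. Density sweeps draw
pairwise-disjoint random marker panels per density (default scheme scaled
from the 1.1k/2.2k/4.4k/22k ×10, 55k ×4, full ×1 reference design) and
average over panels. Masking is verified structurally (no validation id
appears in any training record).

Orderings between models are asserted in tests only when the replicate
mean difference clears twice its Monte-Carlo SE; the model-comparison
suite uses 10 independent scenario replicates of the default
configuration.

## Numerical notes and limitations

- All randomness flows from explicit seeds through SeedSequence-based
  streams keyed by purpose, so components are independently reproducible.
- Relationship matrices are symmetrized defensively and validated to
  1e-10; matrix TSV round-trips at 10 significant digits.
- The sib-sharing spread over a 4-Morgan genome is large (SD ≈ 0.09);
  reduced genomes therefore *overstate* per-pair realized-relationship
  variance relative to a 29-chromosome genome, which benefits IBD-type
  models — orderings, not magnitudes, are the supported conclusions.
- The simulator omits genotyping error, mutation, sex chromosomes,
  crossover interference and selection feedback; the count trait's
  back-transform assumes the surface-area exponent 2/3 exactly.
- `ScenarioConfig.models` controls which reference models are evaluated;
  GBLUP panels are always swept. The CLI subcommands are thin wrappers
  and add no behaviour of their own.
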