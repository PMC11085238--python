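# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Phenotype model and heritability

Trial records follow the two-way model with replicates nested in
environments,

    Y_ijk = μ + E_i + R_j(E_i) + G_k + GE_ik + ε_ijk.

BLUEs treat genotype as fixed with sum-to-zero environment and
replicate-within-environment contrasts; for a balanced design the
adjusted mean equals the raw line mean (the implementation uses that
closed form when the design is balanced, and sequential least squares
with a warning otherwise).  ANOVA mean squares give method-of-moments
components σ²ε = MS_error, σ²GE = (MS_GxE − MS_error)/r,
σ²G = (MS_G − MS_GxE)/(r·e); negatives truncate at zero with a warning.
Line-mean broad-sense heritability is

    h² = σ²G / (σ²G + σ²GE/e + σ²ε/(r·e)),

which collapses to (MS_G − MS_GxE)/MS_G — independent of r and e — when
the components come from the mean squares.  Both routes are computed and
asserted equal (to 10⁻¹² on balanced data without truncation).  Published
trial descriptions sometimes state replicate counts inconsistently, so
`r` and `e` are always explicit inputs, never inferred; the simulated
trial default is 6 environments (years × locations) × 3 replicates.

A note on the precision of ĥ²: with ~175 lines its sampling SD is about
0.006 at h² = 0.9 but about 0.06 at h² = 0.3 (the ratio MS_GxE/MS_G
carries the χ² noise of both mean squares), so per-seed recovery bands of
±0.05 are only meaningful at high heritability; at lower heritability the
estimator is validated as unbiased across seeds.

## Whole-genome regression

**GRM.** VanRaden method 1: G = ZZᵀ/c, Z = X − 2p, c = 2Σp(1−p).
Centering frequencies default to the combined train+test cohort (one
joint GRM over the merged, filtered marker set); training-only
frequencies are an option.  Monomorphic markers are dropped with a
warning.

**REML.** G-BLUP and RR-BLUP share one engine: eigendecompose the kernel
once, profile the restricted likelihood over δ = σ²e/σ²u on the spectrum,
and solve (μ̂, σ̂²u) in closed form at each δ.  The 1-D profile is not
unimodal in general, so a 121-point grid scan over log δ ∈ [−12, 12]
precedes local refinement; variance estimates are floored at 10⁻⁸ and a
boundary flag is raised when the optimum pins at either end (h² → 0
or 1).  With G = ZZᵀ/c and σ²g = c·σ²β the two models are the same model;
the suite asserts GEBV agreement to 10⁻⁶ on held-in and held-out samples.
The identity presumes an interior REML optimum — at a boundary the
c-scaling between the two δ parameterizations is cut off by the shared
search range.  A caveat worth knowing: for an unstructured cohort with
n ≪ m the GRM is close to the identity and the variance ratio is barely
identifiable; REML then sits at a boundary and GEBVs shrink to near zero.
That is correct behaviour, not a failure of the solver.

**Gibbs samplers (BRR, BL, BayesB).**  Single seeded chains, default
10,000 iterations with 2,000 burn-in, thinning 1, posterior means as
point estimates.  Full conditionals are standard: ridge-type normal
updates for effects; scaled-inverse-χ² (df 5) for variances with scales
from the R² = 0.5 heuristic (half of var(y) expected genetic a priori);
inverse-Gaussian for the LASSO's 1/τ²ⱼ with a gamma full conditional for
λ²; Bernoulli inclusion with marker-specific slab variances and a
Beta(2, 2) prior on π for BayesB.  Marker sweeps are numba-compiled;
posterior means of effects are Rao-Blackwellized (conditional means
accumulated rather than sampled values), which cuts the Monte-Carlo
error of the point estimate severalfold at no cost.  Chains track a
running Monte-Carlo SE of the GEBV vector for convergence checks.
Because the hyperprior scales are empirical-Bayes (functions of var(y)),
exact prior-predictive calibration of BayesB inclusion probabilities does
not hold; on pure-noise data mean inclusion sits *below* the prior mean,
which the tests assert as the expected behaviour.

**Prediction.**  Marker-effect models predict new samples as
(X_new − 2p_fit)·β̂ with the *fit's* stored frequencies — new cohorts
never recenter with their own.  G-BLUP predicts through the
cross-relationship block Z_new Z_trainᵀ/c against the stored training
quantities, equal to the joint-GRM conditional expectation.

## Experiments

Within-population prediction uses seeded 10-fold CV: a seeded permutation
split into contiguous near-equal blocks; PA is the per-fold Pearson
correlation between BLUEs and GEBVs averaged over folds (fold-level
averaging, as is conventional, slightly attenuates relative to a pooled
correlation).  Across-population prediction fits once on the union of
training panels and scores the whole test panel.  The composition sweep
evaluates nested prefixes of a distance-ordered panel list plus each
panel singly; the size sweep trains on the s closest candidates under
the mean-distance-to-target ranking; the marker sweep refits on repeated
uniform random SNP subsets (SE = SD/√repeats; the full set is evaluated
once with SE 0).  Group-to-group genetic distance is the mean of all
between-group pairwise Euclidean distances on 0/1/2 dosages (the
aggregation is a package choice; a centroid variant is provided).
Bayesian models inside CV sweeps may run reduced chains (2,000
iterations, 500 burn-in) with a logged warning; single fits default to
the full settings.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis needs:

- **Panels.**  Six panels (A–F, defaults scalable from the full
  1007/607/965/811/508/243 split) in two clusters.  Allele frequencies
  drift hierarchically (Balding–Nichols beta draws): cluster level at
  `fst_between_cluster` (default 0.30), panel level at
  `fst_within_cluster` (default 0.05).  Genotypes are Hardy–Weinberg
  within panel.  Realized Hudson Fst matches the nominal level to within
  sampling error, which the tests verify with an independent estimator.
- **Linkage disequilibrium.**  Markers sit in map blocks (default 10
  consecutive markers) sharing a latent haplotype variable: each
  haplotype draws one uniform per block and each marker copies it with
  probability `ld_strength` (default 0.95), read through a per-population
  phase orientation; ancestral frequencies are blockwise-correlated.
  Marginal frequencies are exact Bernoulli(pⱼ), so Fst, PCA and distances
  are untouched; what the construction adds is within-block tagging (the
  redundancy of a dense SNP array) and **phase drift** — each
  population's orientation flips per marker with probability equal to its
  drift level, so marker–QTL associations are consistent within a
  cluster and partly reversed across clusters.  These two features are
  what make marker-count plateaus and across-population degradation
  possible at all; without LD, every marker is fresh information and
  observed-QTL effects transfer undamaged across any divergence.
- **Breeding population.**  175 F2:6 lines by single-seed descent: F1 of
  two inbred parents selfed five times keeping one offspring per round.
  Meiosis uses Haldane's map function (no interference) on a 20 × 100 cM
  map; residual heterozygosity halves per generation to (1/2)⁵ ≈ 3.1 % at
  F6 and is retained.  A two-locus selfing Markov chain enumerated
  exactly serves as the recombination oracle in the tests.  Parents draw
  from panel A's frequency *and phase* profile, so the RIL population
  clusters inside cluster I and shares its LD, as the real breeding
  population does.
- **Traits.**  Effect pairs for oil and protein at `n_qtl` markers
  (default 200) from a bivariate normal with correlation −0.7; trait
  means anchored midway between the parents' published means (JD12 oil
  17/protein 46; NF58 oil 24/protein 36 — cosmetic only).  G×E is i.i.d.
  normal with σ²GE = 0.2·σ²G; the residual variance is solved from the
  target line-mean h² (default 0.9) through the heritability formula, so
  the realized ANOVA estimate lands on target.  Environment and
  replicate effect SDs (σ²G and 0.25·σ²G) only move level terms.

Not emulated: coalescent-exact LD decay, selection during line
development, genotyping error, unbalanced or non-normal field data, G×E
with environment-specific structure, and any difference in QTL effects
between populations.  The last point matters for interpretation: because
causal loci are genotyped markers with identical effects everywhere,
across-population prediction degrades only through allele-frequency
divergence and LD-phase inconsistency — a shallower decay than real
cultivated-vs-wild contrasts show, where PA collapses to zero.  Passing
tests therefore demonstrate orderings and trends (within > across, PA
falling with distance, plateaus in marker count and training size), not
the field-data magnitudes.

Desk-scale defaults (2,000 markers over 20 chromosomes, panels scaled
×0.2 in the CLI) keep a full pipeline run under a minute; the full-scale
4,141 accessions × ~40k markers are supported but not default.  Test and
acceptance runs use panels of 100–250 samples and 300–2,000 markers —
sizes at which the checked contrasts are comfortably larger than their
Monte-Carlo noise.

## Genotype handling

Dosages use the minor-allele-count convention computed on the analysis
cohort; merging recomputes the orientation on the union (a marker minor
in one cohort may be major in the merged set).  Frequency ties at 0.5
keep the alphabetically first allele as reference for determinism.
Cohorts merge on shared marker ids (id matching, not positional), with
map and allele consistency checked; QC (drop MAF < 0.05, missingness
> 0.10; boundary values kept) runs *after* merging, matching a combined
re-filtering workflow.  Imputation is per-marker mean (continuous, the
regression models consume it directly) or mode; LD-aware imputation is
out of scope.  VCF v4.2 (biallelic SNPs, GT only) and TSV dosage
matrices round-trip bit-exactly, including missing cells; half-missing
GT calls count as missing; multiallelic records are dropped with a
logged count.

## Reproducibility

Every stochastic component takes an explicit seed (numpy Generator);
identical config + seed reproduces byte-identical artifacts, which the
CLI tests assert.  Pipeline artifacts embed a 12-hex config hash and the
seed as commented header lines; `soygp report` refuses to combine
artifacts whose data lineage differs.  Model fits serialize to JSON with
effects, centering frequencies, variances and training ids, so stored
predictions are reproducible bit-for-bit from the file.
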