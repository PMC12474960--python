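# Methods

`jucara` implements the statistical chain used to characterize a founder
collection of juçara palm (*Euterpe edulis*) — or any germplasm panel with
the same data shapes: replicated phenotypes on a set of genotypes, plus
diploid codominant marker genotypes on (a subset of) the same individuals.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data tests do and do not show.

## Mixed models and REML

All phenotypic inference runs through one Gaussian mixed-model engine,

y = X b + Z u + e,  u ~ N(0, G),  e ~ N(0, R),

with four pre-wired forms matching the four trait groups of such trials:

| group | fixed | random | residual R |
|---|---|---|---|
| biometric (fruit/seed measures) | intercept + replicate | genotype (IID) | homogeneous |
| emergence | intercept + replicate + sampling group | genotype + elevation class (IID each) | one variance per sampling group |
| growth | intercept + replicate + evaluation time | genotype + genotype-by-time | one variance per time |
| physiological (Fv/Fm) | intercept + replicate + time | genotype | one variance per time |

The genotype-by-time covariance among the t evaluation times supports IDV
(σ² I), DIAG, compound symmetry (CS) and unstructured (US) forms, applied as
a Kronecker product with the identity over genotypes.

**Identifiability.** A CS or US among-time matrix contains a
compound-symmetric component, so a separate IID genotype main effect is not
identified jointly with it: shifting c between σ²_g and G_gm − cJ leaves the
likelihood unchanged. The engine therefore treats CS/US candidates as
absorbing the genotype main effect; the identified per-time genotypic
variance is then the diagonal of the fitted matrix. The default candidate
set for model selection is IDV and DIAG (both identified alongside the main
effect), with CS/US available explicitly.

**Estimation.** The restricted log-likelihood is maximized directly over
unconstrained transformed parameters — log variances, a log-Cholesky factor
for US, a bounded correlation for CS — so nonnegativity and positive
semidefiniteness hold by construction and boundary estimates appear as
variances shrinking to ~0 (reported as estimated; tests treat < 1e-6 as the
boundary). Each likelihood evaluation is O(q²) in the number of
random-effect levels: per-residual-group Gram matrices of [X Z y] are
precomputed once, and the Woodbury identity reduces everything to a q×q
Cholesky — no n×n matrix is ever formed. The optimizer is L-BFGS-B followed
by a mandatory Nelder-Mead refinement (tight tolerances with `polish=True`,
a short budget otherwise, restarted up to three times). Numerically singular
corners of the parameter space (e.g. residual variance → 0 when the
intercept lies in the genotype design's column space) are kept finite by an
escalating-jitter Cholesky and, beyond that, a smooth penalty, so line
searches that overshoot recover instead of stalling. Convergence requires
either optimizer success or a final restart that moves the objective by less
than 1e-5 relative; the reported log-likelihood trace is the incumbent best,
monotone by construction. On balanced one-way data the engine reproduces the
closed-form ANOVA estimators to better than 1e-6 relative (and ~4e-4 in the
fast unpolished mode used inside simulation loops).

**BLUPs, PEV, genetic parameters.** Genotype BLUPs and the full
prediction-error-variance matrix come from the inverse coefficient matrix of
the mixed-model equations at the REML optimum. Generalized heritability is
Cullis's H² = 1 − mean Δ_BLUP / (2 σ̂²_g), averaging var(ĝ_i − ĝ_j) over all
genotype pairs (the mean-PEV variant is available via `method='mean-pev'`).
Prediction accuracy is r_i = sqrt(1 − PEV_ii / σ̂²_g), clamped for
PEV exceeding σ̂²_g by ≤ 1e-8. Note the balanced-case identity
mean r ≈ sqrt(H²) holds up to an O(1/n_genotypes) intercept-uncertainty term
in the PEV diagonal.

**Tests and criteria.** The LRT for a variance component uses a plain χ²
with df = parameter difference, as is conventional in this literature;
because the null lies on the boundary this is conservative, and the
0.5χ²₀+0.5χ²₁ mixture is available behind `boundary=True`. Information
criteria: AIC = −2ℓ + 2p and BIC = −2ℓ + p log n with p the number of
(co)variance parameters and n the observation count; BICc replaces n by the
REML effective sample size n − rank(X). Ties in model selection go to the
candidate with fewer parameters.

**Genetic correlations.** r_g = σ̂_g12 / sqrt(σ̂²_g1 σ̂²_g2) from a bivariate
REML fit with unstructured 2×2 genetic and residual covariances
(log-Cholesky parameterized), over units where both traits are observed. A
fast fallback correlates univariate BLUPs (`method='blup'`; slightly
deflated by shrinkage). No exact sampling distribution exists for r_g here;
significance is approximated by a t-test with effective n = number of
genotypes and labeled as such.

## Derived traits

Emergence series (new emergents per inspection day, boxes of 25 sown seeds)
yield Maguire's emergence speed index ESI = Σ n_i/t_i, Labouriau's mean time
to emergence MTE = Σ n_i t_i / Σ n_i (NaN when nothing emerges — never 0),
and the emergence percentage. Dickson's quality index is
DQI = TDM / (SH/DSB + SDM/RDM) with root dry mass derived as RDM = TDM − SDM
(only shoot and total masses are recorded). Height enters in cm and basal
diameter in mm, as recorded, without unit conversion; since sources rarely
state whether the diameter is converted, `diameter_in_cm=True` switches the
convention and the choice is stamped in the pipeline run log.

## Association analysis

Phenotypic correlations are Pearson coefficients among genotype-level trait
values on pairwise-complete data, with two-sided t-tests (n−2 df). Before
path analysis, collinearity among explanatory traits is screened by the
variance inflation factor VIF_i = [C⁻¹]_ii; traits are removed iteratively —
highest VIF first, recomputing after each removal, because removing one
collinear trait changes all remaining VIFs — until all VIF ≤ 5. Path
analysis then solves C p = r_y on the retained traits: direct effects p,
indirect effect of trait i via j equal to C_ij p_j, R² = pᵀ r_y, and
residual variable effect sqrt(1 − R²). The decomposition identity
(direct + indirect = correlation, exactly) and R² = Σ p_i r_i are enforced
to 1e-10 in tests. The analysis runs on the phenotypic correlation matrix by
default (the convention for a single seedling-quality response); the genetic
matrix can be passed instead.

## SSR diversity

Per locus, over genotyped individuals only (sample sizes legitimately differ
by locus): observed heterozygosity Ho; the sample-size-corrected expected
heterozygosity He = N/(N−1)(1 − Σ p_i²); F = 1 − Ho/He (negative F =
heterozygote excess, reported as computed, truncation left to the user); and
PIC = 1 − Σ p_i² − Σ_{i≠j} p_i² p_j², the cross term taken over ordered
pairs exactly as defined. One caveat the tests document: under random-mating
sampling of 2N allele copies the exactly unbiased correction would be
2N/(2N−1), so the N/(N−1) form overshoots the plug-in gene diversity by at
most (1−Σp²)/(2(N−1)) — negligible at typical N but visible in a 500-sample
Monte-Carlo average.

## Divergence

Genotypic distance is the standardized mean Euclidean distance (DEMP) over
SD-scaled BLUPs, averaged over the traits complete in both genotypes
(range-scaling behind `scale='range'`). Molecular distance is the unweighted
shared-allele index: per locus scored in both genotypes, similarity =
(alleles in common, counting multiplicity)/2 ∈ {0, 0.5, 1}; distance = 1 −
mean similarity over shared loci. This definition is isolated in one
function for easy substitution since "unweighted index" is used loosely
across software manuals.

Matrices are normalized to [0, 1] by dividing by the maximum off-diagonal
entry — min–max mapping would send the closest pair to distance 0,
destroying identity of indiscernibles, but is available behind
`method='minmax'` — and fused by the entrywise mean over the shared label
set. Clustering is UPGMA (scipy average linkage; deterministic) cut at the
Mojena threshold mean(h) + k·SD(h) over fusion heights (sample SD, k = 1.25
default): groups are the clusters just below the threshold. The Mantel test
correlates lower-triangle vectors with a one-sided upper-tail permutation
p = (1 + #{r_perm ≥ r_obs})/(B + 1), B = 5000 by default, under joint
row/column permutation of one matrix, with an explicit seed.

## Synthetic data

The generators draw from exactly the models above, with defaults mirroring
the emulated trial: 72 genotypes; 10 replicates for biometric and growth
traits; 4 boxes × 25 seeds for emergence, counted every 2 days; 5 evaluation
times for growth; 59 genotyped individuals at 8 SSR loci with 8–20 alleles
per locus. One root seed feeds deterministic per-generator substreams, so
adding a generator never perturbs another. SSR genotypes follow
P(homozygote i) = p_i² + F p_i(1−p_i), P(heterozygote ij) = 2p_i p_j(1−F),
with infeasible negative F clipped to the per-locus bound (warning naming
the locus) or rejected with `clip=False`. Missingness is MCAR at a
configurable rate (default 0: balanced fixtures).

The planted-cluster panel (for the fused-distance recovery test) places 3
origins × 20 genotypes with trait centroids 8 within-cluster SDs apart along
distinct axes — every trait carries between-cluster signal, since DEMP's SD
standardization cancels separation on any pure-noise trait — and gives each
origin a disjoint allele block per locus with a 0.8 major allele. This is
the "strongly differentiated origins" regime; under it the fused
UPGMA/Mojena pipeline recovers the 3 groups in ≥ 90% of runs.

What the synthetic tests do **not** show: real trials have spatial field
structure, non-Gaussian residuals, genotyping errors and null alleles,
linkage between loci, and informative (not MCAR) missingness — none of which
are simulated. Passing recovery tests demonstrates correctness of the
estimators under their own assumptions, not robustness to violations.

## Numerical and scale choices

Simulation-heavy tests are sized to run comfortably on one CPU: H² recovery
at the emulated trial's own scale (72×10, 300 Monte-Carlo replicates — the
mean of Ĥ² at true H² = 0.3 sits ≈ 0.278 because the concave σ̂²_g → H² map
plus boundary truncation biases the mean down ~0.02, and the MC error of a
small batch would otherwise dominate the comparison); bivariate r_g at 72×5
over 50 replicates; unstructured G_gm at 40×4×3 over 50 replicates; Mantel
null calibration with B = 99 over 200 runs. Dendrograms serialize to newick
with branch lengths derived from fusion heights; distance matrices to
labeled CSV and lower-triangle PHYLIP.

## Known limitations

- No pedigree/genomic relationship matrices, spatial models, or Bayesian
  estimation; no Hardy–Weinberg exact tests, null-allele handling, or
  F-statistics hierarchy; no bootstrap support on dendrograms.
- The bivariate fit assumes both traits share experimental units; traits
  measured on disjoint material can only use the BLUP-correlation fallback.
- Likelihood-based intervals/SEs for variance components are not reported;
  model comparison is via LRT and information criteria only.
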