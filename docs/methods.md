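# Methods

This note documents the statistical machinery, the numerical choices, and
the limits of what the synthetic experiments demonstrate.

## Trial adjustment

Each (trait, environment) trial is fitted as
y_jkm = μ + L_j + r_k + b_m(k) + e_jkm with fixed line effects and
independent random replicate and block-within-replicate effects,
r_k ~ N(0, σr²), b_m(k) ~ N(0, σb²), e ~ N(0, σe²). Variance components are
estimated by EM-REML on Henderson's mixed-model equations in variance-ratio
form: the coefficient matrix carries λ_i = σe²/σ_i² on each random block,
updates are σ_i² ← (û_i′û_i + σe²·tr(C^{ii}))/q_i and
σe² ← (y′y − ŝ′W′y)/(n − rank X). Iteration stops when every component's
relative change falls below 1e-8 (cap 500 iterations); components are
floored at 1e-10 and λ capped at 1e12 so a collapsing component cannot
destabilize the solve. Line BLUEs are the fixed-effect solutions (full
line-indicator coding; identical to any other identifiable coding).

A second fit with lines random (intercept the only fixed effect) supplies
σg² for heritability. The reported `var_error` comes from the fixed-line
(BLUE) fit; the two error variances are near-identical in practice.
Heritability uses the entry-mean formulas with r the harmonic mean of
per-line plot counts, the standard generalization when replication is
uneven. Single-replicate trials fix σr² = 0; if every replicate holds one
block the block term is dropped as fully confounded; if there is exactly one
plot per line the fixed-line model has no residual degrees of freedom, so
BLUEs are the observed values and the error variance comes from the
random-line fit.

## Relationship kernels

* **MAF filter**: markers with minor-allele frequency (computed on
  non-missing dosages of the analyzed lines) below the cut-off are dropped;
  default 0.05. Missing dosages are then replaced by the marker mean.
* **G (VanRaden, method 1)**: columns centered at 2p_l, single global
  divisor 2 Σ p_l(1−p_l). Allele frequencies come from the analyzed panel
  itself. A per-marker-standardized variant
  (`vanraden_g_standardized`) is available for sensitivity analyses; the
  two agree in expectation under Hardy–Weinberg proportions. On a fully
  inbred panel the G diagonal averages ≈ 2 rather than 1 — expected, since
  inbreds carry twice the Hardy–Weinberg heterozygosity deficit.
* **A (tabular method)**: individuals processed parents-first;
  a_ii = 1 + F_i with F_i = a_{sire,dam}/2; unknown parents contribute
  nothing. Validated against two independent oracles: a recursive
  coefficient-of-kinship computation and a 10⁵-replicate gene-dropping
  Monte-Carlo (unique founder alleles dropped through the pedigree,
  a_ij = 2 × kinship).
* **Cell-level kernels**: with cells ordered environment-major/line-minor,
  a main-effect expansion is (Z K Z′)_{cc′} = K(line c, line c′) and an
  interaction kernel is that expansion Hadamard-multiplied by the
  same-environment indicator, hence block-diagonal by environment. All
  cell-level structures are built from one shared incidence map so the AE
  and GE kernels can never silently misalign.
* **PSD policy**: kernels are validated to symmetric with smallest
  eigenvalue ≥ −1e-8 (relative); eigenvalues in (−1e-8, 0) are clipped to
  zero, anything more negative raises an error carrying the offending
  eigenvalue.

## Model fitting

Every model term — including the iid E and L factors, treated as
identity-kernel expansions — is represented on the training cells by a
factor B with B B′ = K (the term's kernel restricted to those cells) and
B′B diagonal. Identity terms use the raw incidence matrix (B′B = level
counts); main expansions use the line-kernel eigendecomposition followed by
a thin SVD of Z U Λ^{1/2}; interaction terms are eigendecomposed per
environment block. Eigenvalues ≤ 1e-10 are dropped. In this basis each
coordinate of a term's effect has an independent Gaussian full conditional,
so one Gibbs update costs two matrix-vector products per term.

**Gibbs sampler** (defaults: 12 000 iterations, 2 000 burn-in, thin 5,
prior df 5): variance components get scaled-inverse-χ² full conditionals.
Prior scales follow an R²-partition of the response variance — residual
share 0.5, the rest split equally across terms, each term's share divided
by its kernel's mean diagonal — so priors are weakly informative at the
data's scale regardless of kernel normalization. The intercept has a flat
prior. Fixing the variances (`fixed_variances`) turns the sampler into a
Monte-Carlo evaluator of the BLUP, which is how sampler correctness is
verified against the exact mixed-model-equation solver (`mme_solve`).

**Response standardization** (default on): the response is centered and
scaled within each environment on training records only, and predictions
are back-transformed. Per-environment Pearson correlations are invariant to
this, so prediction-ability comparisons are unaffected; variance components
are reported on the fitting scale. Experiments that recover generative
variances switch it off.

**Prediction.** For cells outside the training set, each term's effect has
a multivariate-normal conditional given the training-cell effects, with
mean K_mo K_oo⁺ u_obs and covariance σ²(K_mm − K_mo K_oo⁺ K_om). The exact
solver returns the conditional mean (the BLUP). The Gibbs fit draws the
masked effects from the full conditional — mean plus covariance noise — per
retained sample and averages, i.e. proper posterior-predictive sampling.
The distinction matters exactly where a term carries no information: under
M1, a line never phenotyped has a conditional-mean prediction identical for
every line in an environment (correlation undefined), whereas
posterior-predictive draws leave small Monte-Carlo noise that averages to
zero — which is why M1/CV1 abilities are measurable and sit within ±0.05 of
zero rather than being undefined, mirroring how general-purpose Bayesian
samplers behave. Environments never seen in training are refused (neither
CV scheme predicts new environments); new lines draw their A/G
contributions from kernel relatedness to training lines.

Undefined correlations (zero-variance vectors, fewer than 3 pairs) are
recorded as missing and excluded from averages with the exclusion count
reported; coercing them to zero would bias model comparisons.

## Cross-validation

CV1 permutes lines once per replicate and splits them into five near-equal
folds; a fold masks every cell of its lines. CV2 deals each
multi-environment line's cells round-robin across folds in a seeded random
order, rotating the starting fold over a seeded line order — fold sizes are
balanced, every masked line keeps a training cell, and lines observed in a
single environment are never masked. A pure-random cell allocation is
available as an option. Partition seeds derive only from (master seed,
scheme, replicate) and sampler seeds from (master seed, scheme, model
identity, replicate, fold), so adding or removing models never perturbs the
partitions and per-model results are stable across model lists.

Aggregation is mean-over-runs within environment first, then across
environments for grand means. Model comparison fits a two-way ANOVA without
interaction (model + environment block) on per-environment mean
correlations and applies Tukey's HSD with the studentized range at
α = 0.05, reported as a compact letter display.

## Synthetic data

The generator emulates an elite inbred panel in an international trial
series: founders receive independent biallelic genotypes with frequencies
uniform on [maf_min, 1−maf_min]; descendants come from recorded biparental
crosses, sampling one gamete per parent and doubling one of them per marker
(a single-seed-descent shortcut keeping dosages in {0, 2}); markers whose
realized MAF falls below the floor are regenerated so the returned panel is
already past the filter. Phenotypes follow
y = μ + E + L + g + a + Eg + Ea + rep + block + e with g ~ N(0, G σg²),
a ~ N(0, A σa²) and the interactions drawn independently per environment
from the corresponding kernel — exactly the covariance the interaction
models assume. G and A are rescaled to unit mean diagonal inside the
generator so every configured variance is the realized per-line variance of
its effect. A fraction of line×environment cells is removed completely at
random (each line keeps ≥ 1 environment), replicate/block layouts assign
lines to equal incomplete blocks by seeded permutation, and the truth
record stores all components plus each line's total genetic value per cell.

`wami_like_preset()` encodes the dimensions of a well-known elite
spring-wheat association panel — 287 lines, 18 environments, 2 replicates,
5 % MAF floor, ~15 000 markers — with variance components chosen so
across-environment entry-mean H² ≈ 0.4 (line-variance total 0.055 against
G×E 1.0 and residual 1.0): a grain-yield-like trait dominated by G×E.
Block counts and the missing-cell rate are stated assumptions, not
reconstructions of any real field layout.

What the generator does **not** emulate: linkage and LD decay (markers are
independent given the pedigree), selection or drift across generations,
spatial field trends, non-MCAR missingness, and environmental covariates.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behaviour of the models under the assumed covariance structure,
not performance on any particular real dataset.

## Standard experiment sizes

The canned experiments (`gxepred.experiments`) fix the package's benchmark
conditions: parameter recovery simulates 300 lines × 10 environments at
σE²=1, σg²=0.6, σEg²=0.4, σe²=1 (one plot per cell) and refits M5 on the
raw scale with the generative (unit-diagonal) kernel, 2 000 iterations,
500 burn-in — medians over 10 seeds land within ±30 % of each component,
with σg² the hardest because the iid L term absorbs part of the genomic
signal (the two are weakly separated when the truth has σL² = 0).
Sampler-vs-BLUP agreement uses a 60-cell instance and all seven models at
fixed variances. CV experiments use 100 lines × 6 environments with
shortened chains (1 200 iterations); the M1/CV1 null calibration uses 40
replicates (200 runs) purely to tighten the Monte-Carlo error of the
per-environment means, and the directional contrasts (CV2 ≥ CV1 for M3,
M5 ≥ M3 under CV2 with σEg² > 0, M5 ≈ M3 without) use 10-seed medians of
2-replicate runs.

## Known limitations

* EM-REML is simple and robust but slow near the boundary (components
  floored rather than profiled out); no standard errors are reported for
  trial-level variance components.
* The Gibbs sampler assumes a single residual variance across environments
  (after optional per-environment standardization); heterogeneous residual
  models are out of scope.
* The iid line effect L and a genomic kernel with near-unit diagonal are
  weakly identified when one of them is truly zero; variance partitions
  between them should be interpreted jointly.
* Dominance/epistasis kernels, single-step H matrices, marker-by-
  environment decompositions, multi-trait models and environmental-
  covariate kernels are deliberately not implemented.
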