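# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where published analysis
protocols leave details open.

## Data model

Three sample-aligned blocks: a genus-level composition (rows on the
simplex; raw counts retained when available), a dietary nutrient table, and
one or more metabolite intensity tables, plus per-sample covariates
(gender, total caloric intake, batch, BMI). All containers wrap pandas
DataFrames; alignment is by inner join on sample id with the first table's
order.

## Preprocessing

Metabolites: below-detection cells are imputed with the per-variable
minimum of observed values; each variable is rescaled so its median is 1;
the rank-based inverse-normal transform (INT) with the Blom offset
c = 3/8 maps values to Φ⁻¹((r − c)/(n − 2c + 1)) with average ranks for
ties; variables that still fail a Shapiro–Wilk test at α = 0.05 (heavy
ties, near-zero variability) are dropped.

Diet additionally receives the residual method — each variable replaced by
its least-squares residual on [1, total kcal, gender], standardized to mean
0 / SD 1 — and deduplication: variables linked when pairwise Spearman
ρ > 0.9 (signed: the clusters of interest are near-copies), clusters taken
as connected components, and the member with the highest mean within-
cluster correlation kept (ties broken by variable id). Metabolites are
deliberately not energy/gender-adjusted; the residual method addresses the
intake-scale confounding specific to nutrient variables.

Decisions: the Blom offset is the standard choice where the INT reference
leaves it open; total kcal enters untransformed by default with a log
option; the screen runs once, after INT and before the residual step.

## Global dependence: distance correlation t-test

For blocks X (n × p) and Y (n × q), pairwise Euclidean distance matrices
are U-centered:

    Ã_ij = a_ij − a_i·/(n−2) − a_·j/(n−2) + a_··/((n−1)(n−2)),  Ã_ii = 0,

whose rows sum to zero identically. The bias-corrected distance correlation
is r* = ⟨Ã,B̃⟩/√(⟨Ã,Ã⟩⟨B̃,B̃⟩) with the off-diagonal inner product, and
t = √(v−1)·r*/√(1−r*²), v = n(n−3)/2, is referred to a Student t with
v − 1 degrees of freedom, one-sided (dependence inflates r*). This
construction is numerically identical (verified to 10⁻¹⁶) to the modified
A*-matrix formulation used by the reference R implementation.

The t reference is asymptotic in the block dimensions. At n = 30 and
p = q = 10 the measured type-I error at α = 0.05 is ≈ 0.058 (20 000-rep
estimate), i.e., very mildly liberal; it converges to the nominal level by
p = q ≈ 30. Compositions enter as raw proportions (a clr option exists but
is off by default). Edge classes for the block-pair table: "thick"
p < 10⁻⁵, "thin" 10⁻⁵ ≤ p < 0.1, "none" otherwise.

## Metabolite modules

Unsigned weighted-correlation network: adjacency |cor|^β with β the
smallest power in 1..20 whose connectivity distribution fits scale-free
topology at R² ≥ 0.8 (argmax fallback); topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
hierarchical clustering of 1 − TOM; static cut; branches smaller than
min_module_size = 10 relabeled "unclustered". Each module is summarized by
the standardized first principal-component score of its standardized
members, sign-oriented to correlate positively with the module mean
profile; downstream analyses use module eigenvalues alongside raw
unclustered metabolites.

Numerical choice: a fixed cut height is fragile on TOM dendrograms — as β
grows all merge heights compress toward 1 and any constant threshold either
captures everything or nothing. The default cut is therefore placed in the
largest gap among the upper half of the merge heights, which is invariant
to that compression; an explicit numeric height can be forced. Module
counts are configuration-sensitive, so tests validate recovery of planted
structure rather than any fixed count.

## Sparse linear log-contrast selection

The model for response y and log relative abundances Z of the top-k
(default 50) most abundant genera, re-closed:

    min (1/2n)‖y − β₀1 − Zβ‖² + λ‖β‖₁   s.t.  Σ_j β_j = 0.

Zeros are handled by multiplicative replacement (δ = half the smallest
nonzero proportion of the matrix; nonzero entries of a row scaled down to
keep the unit sum) before the log. The zero-sum constraint is what the
composition's unit sum induces, and it delivers exact invariance to
per-sample count rescaling (tested to 10⁻⁸).

Solver. The constraint is dualized: for a multiplier ν the inner problem is
an ordinary lasso with linear term q − ν, solved by Gram-matrix coordinate
descent with an incrementally maintained gradient; the constraint gap
s(ν) = Σβ(ν) is monotone and piecewise linear in ν, so a safeguarded
secant/bisection drives it to zero. A coarse solution then seeds an exact
active-set polish — the equality-constrained KKT system on the support with
signs fixed, dropping sign flips and admitting margin violators — giving
machine-precision stationarity and Σβ = 0 wherever the Gram matrix has full
rank on the support. On rank-deficient Grams (bootstrap resamples with
k close to the number of distinct samples) all effort is bounded; solutions
are exact except in the extreme overfit tail (λ below λ_max/10³ past the
rank), a region cross-validation never selects. λ_max = (max q − min q)/2
exactly; the grid is 100 (or 40 for large scans) log-spaced values spanning
4 decades; λ = 0 uses the closed-form bordered KKT solve.

Tuning and stability. 10-fold CV with seeded fold assignment and the
minimum-mean-error rule (ties resolve to the sparser end of the grid); 100
bootstrap resamples re-run the full CV tuning, and a genus is associated
when selected in strictly more than 70. Within a bootstrap replicate, CV
folds are grouped by original sample id: duplicated draws of one subject
never straddle the train/validation boundary. Without this grouping the
leaked duplicates systematically favor overfit λ and push null per-taxon
selection counts past the threshold (~15% false selection under the null);
with it the null rate is below 1% and sensitivity on planted effects is
unchanged. Replicates with a constant resampled response are skipped and
logged; the denominator stays at 100. Reported coefficients are means over
the replicates in which a taxon was nonzero; a full-data refit is also
available.

## Compositional mediation

For a triplet (diet d, composition X, metabolite y): the a-path vector is
the per-coordinate OLS slope of clr(X) on d; the outcome model is least
squares of y on [1, d, log X] with the zero-sum constraint on the taxon
block (bordered KKT solve; if the taxon block is not estimable at the
sample size, a CV-tuned zero-sum lasso selects a support that is then refit
without penalty, with a warning). Because Σb = 0, b'clr(x) = b'log(x), so
per-taxon indirect effects a_j·b_j are well defined; the total indirect
effect is their exact sum, and on linear data total effect ≈ direct + total
indirect (verified at n = 1000 within 0.05). Uncertainty: joint percentile
bootstrap (default 500 replicates, 95% level) for the total and per-taxon
effects. Optional covariates are residualized out of d, y and log X before
fitting. Candidate triplets are diet–metabolite pairs whose
stability-selected genus sets intersect. Flags use unadjusted 95% CI
exclusion of zero and are labeled as such.

## Enterotypes and interactions

Distances: Euclidean on proportions, Bray–Curtis, and classical binary
Jaccard on presence/absence (proportion > 0). PAM: when the medoid search
space is small (C(n,k) ≤ 20 000, which covers k = 2 at cohort scale) the
optimum is found by exact enumeration; otherwise deterministic greedy BUILD
plus best-improvement SWAP. The (distance, k) pair maximizing average
silhouette width over k = 2..6 is chosen; a maximum below 0.25 is flagged
as weak structure. Classical PCoA (negative eigenvalues zeroed) provides
ordination on the chosen distance.

Caveat: binary Jaccard degenerates when taxon richness is low enough that
presence saturates (many exactly-zero distances inflate silhouette); at the
realistic 130-genus scale with a rare tail this does not occur.

Characterization uses Welch two-sample t tests on INT-transformed taxon
(and family-aggregated) abundances and on metabolites, reported with
unadjusted p — the variables are strongly correlated, and marginal
screening is labeled as such. Interactions: for each diet–metabolite pair,
OLS of m ~ 1 + d + E + d·E with E a 0/1 enterotype indicator (n − 4
degrees of freedom), two-sided t test on the interaction term, per-
enterotype simple slopes reported; no covariates by default (config-
exposed). Stratified follow-ups report per-stratum slope, t-test p and
Spearman correlation, skipping strata below 5 samples.

## Synthetic cohorts and what they show

The generator plants every effect the pipeline estimates and records it
exactly, at the cohort's scale: n = 136 subjects (enterotype split 54:82,
deterministic by default), 130 genera, 91 dietary variables, 200
metabolites by default (812 with 8 modules in the full-scale preset).

* Microbiome: logistic-normal-multinomial — per-sample log abundances are
  Gaussian around the sample's enterotype center (SD 0.8), closed through
  softmax, counted by a multinomial at log-normal depth (median 10⁵). Base
  log abundances decay linearly over ±4, giving a graded top-50 and a rare
  tail with realistic absences. The logistic-normal choice is deliberate:
  planted effects must be linear on the log/clr scale where the
  log-contrast model operates. The marker ("Ruminococcaceae-like") family
  of 8 taxa sits at mid abundance rank and is raised by 3 log units in
  enterotype 2 — it swings from minor to dominant between enterotypes
  while closure barely moves the other families, so the family is both the
  clustering signal and the top-ranked group difference, as in real gut
  enterotypes.
* Diet: Gaussian-copula blocks with prescribed within-block Spearman
  correlation (Pearson ρ = 2 sin(πρ_s/6) calibration); default three
  blocks of sizes 3/3/4 at ρ_s 0.93–0.95 exercise the dedup stage; the
  metadata table carries gender and log-normal total kcal.
* Metabolome: module factors (loading 0.9) + sparse zero-sum taxon effects
  on log composition + diet main effects + diet × enterotype interactions
  (δ = 0.5) + Gaussian noise, with planted taxa drawn from the top-50
  abundance pool so they remain analyzable. Mediation triplets perturb the
  latent log abundances of three taxa by heterogeneous a-paths (a uniform
  a-path paired with a zero-sum b would plant an exactly-zero total
  indirect effect) and add a zero-sum b-path to the outcome; the recorded
  total indirect effect is exactly Σ a_clr,j·b_j. A dedicated mediation
  benchmark fixes the planted total at 0.40.
* Noise scale: the metabolite noise SD defaults to 0.75, set by an a
  priori power computation — with a standardized diet variable and the
  54:82 split, the interaction coefficient's standard error at n = 136 is
  ≈ 0.175·σ, so δ = 0.5 is detectable at α = 0.01 with ≈ 0.89 power at
  σ = 0.75 (and only ≈ 0.61 at σ = 1). Effect scales are otherwise
  arbitrary and documented here; they are chosen for detectability at
  n = 136, not estimated from any real data.

What passing tests on these cohorts do not show: real diet–microbiome
data have measurement error in self-reported intake, taxon-specific
overdispersion and covariance, batch structure, and non-Gaussian metabolite
tails that the generator does not emulate; recovery rates here are
best-case for the stated effect sizes.

## Problem sizes and runtime choices

The validation benchmarks run at the cohort scale: stability selection is
evaluated over 20 planted datasets (100 bootstraps each, 40-lambda grid),
mediation over 50 repetitions at n = 500 (500-replicate bootstrap CIs for
the null-coverage check), dcor calibration over 2000 replicates at n = 30,
and interaction calibration over 2500 null pairs. These sizes give
binomial/Monte-Carlo standard errors comfortably inside the asserted
margins while keeping a full validation run to a few minutes on one CPU.

## Known limitations

* The dcor t-test is mildly liberal for blocks of ~10 variables (see
  above); permutation-based alternatives are out of scope.
* The zero-sum solver returns bounded-effort approximate solutions in the
  deep-overfit tail of rank-deficient bootstrap problems; single fits
  always verify a KKT residual ≤ 10⁻⁶ and raise otherwise.
* Module detection parameters (power target, gap cut, minimum size) are
  heuristics; module counts should be treated as configuration-dependent.
* Mediation flags are unadjusted and causal only under no-unmeasured-
  confounding; no sensitivity analysis is provided.
* PAM above the enumeration threshold is a deterministic local search
  without an optimality certificate.
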