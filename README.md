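# triomix

Integration of diet, gut microbiome, and metabolome data from
cross-sectional human cohorts. The package implements the full analysis
chain used in multi-omic diet–microbiome studies — global block-level
dependence testing, metabolite module construction, compositional taxon
selection, compositional mediation, and enterotype-stratified interaction
analysis — together with a synthetic-cohort generator with fully recorded
ground truth, so that every stage can be validated on planted effects.

## Who it is for

Statistical and computational biologists analyzing feature tables of the
form samples × genera (16S relative abundances), samples × nutrients
(FFQ- or food-record-derived), and samples × metabolites (MS intensity),
who need the microbiome treated as what it is: a composition on the
simplex, where only ratios carry information.

## The models

**Global dependence.** For two blocks of variables observed on the same
samples, the bias-corrected distance correlation r\* is built from
U-centered Euclidean distance matrices; under independence

> t = √(v−1) · r\*/√(1−r\*²),  v = n(n−3)/2

follows a Student t distribution with v−1 degrees of freedom, valid when
block dimensions exceed the sample size.

**Sparse log-contrast selection.** A dietary or metabolite variable y is
regressed on the log relative abundances of the top-50 genera under the
zero-sum constraint that the unit-sum of a composition induces:

> min (1/2n)‖y − β₀1 − Zβ‖² + λ‖β‖₁  subject to Σⱼ βⱼ = 0,

with λ tuned by 10-fold cross-validation. Selection is stabilized over 100
bootstrap resamples; a genus is declared associated when it enters the
selected model in strictly more than 70 of them. The constraint makes every
fit invariant to per-sample count rescaling.

**Compositional mediation.** For a diet → microbiome → metabolite triplet,
an a-path vector (clr composition on diet) and a b-path vector (outcome on
diet + log composition, zero-sum on taxa) combine into per-taxon indirect
effects aⱼbⱼ; their sum is the total mediation effect, with percentile
bootstrap confidence intervals.

**Enterotypes.** Partitioning-around-medoids under Euclidean, Bray–Curtis
and binary Jaccard distances, with (distance, k) chosen by maximum average
silhouette; clusters are characterized by Welch t tests on INT-transformed
abundances, and diet × enterotype interactions on metabolites are tested by
OLS (m ~ 1 + d + E + d·E).

**Metabolite modules.** Weighted-correlation networks (|cor|^β adjacency at
a scale-free soft power, topological overlap, average-linkage clustering,
static gap cut); each module is summarized by its standardized first
principal-component score ("module eigenvalue").

## Worked example

```python
import triomix
from triomix.logcontrast import top_k_taxa, log_design

# a synthetic 136-subject cohort with recorded ground truth
study = triomix.simulate_study(seed=7)
comp, diet, meta, truth = (study["composition"], study["diet"],
                           study["metadata"], study["truth"])

# preprocessing: INT + Shapiro screen (+ energy/gender residuals and
# Spearman-0.9 dedup for diet)
diet_n, report = triomix.preprocess_diet(diet, meta)
metab_n, _ = triomix.preprocess_metabolites(study["metabolites"])

# global gut-microbiome ~ metabolome dependence
print(triomix.dcor_ttest(comp, metab_n, block_x="gut", block_y="metabolome"))

# stability-selected genera for a diet variable that (per the recorded
# truth) perturbs three genera
trip = truth.mediation_triplets[0]
Z = log_design(top_k_taxa(comp, 50))
prof = triomix.stability_select(Z, diet_n.data[trip["diet"]].to_numpy(),
                                n_bootstrap=100, threshold=70, seed=0)
print("planted:", sorted(trip["a_paths"]))
print("selected:", prof.selected)

# enterotypes
print(triomix.choose_enterotypes(comp).summary())
```

Output from this exact session:

```
DcorResult(gut ~ metabolome: r*=0.0192, t=1.830, dof=9043, p=0.0336, n=136)
planted: ['genus_029', 'genus_032', 'genus_038']
selected: ['genus_029', 'genus_032', 'genus_038', 'genus_048']
Enterotype model: PAM, bray-curtis distance, k=2
  average silhouette width: 0.349
  cluster sizes: E1=54, E2=82
  medoids: S005, S105
  PCoA axis variance: 40.9%, 6.3%
```

The gut–metabolome dependence is detected globally (one-sided p ≈ 0.03 at
this effect size); the three genera the diet variable truly perturbs are
selected in 100/100 bootstrap replicates (one correlated neighbor rides
along at 83/100); and clustering recovers the two planted enterotypes and
their 54:82 split exactly.

The same stages run from the shell:

```sh
triomix all --seed 7 --out results/run1
```

writes per-stage TSV tables (normalized inputs, module eigenvalues, the
global dependence table, long-form association and mediation tables,
enterotype labels and interaction scan) plus a JSON manifest of seeds and
thresholds. Rerunning the same configuration reproduces every file
byte-for-byte.

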