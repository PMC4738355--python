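# Methods

`pairedsurv` quantifies how much survival-relevant information resides
in three views of a paired tumor/normal expression cohort — the tumor
matrix, the paired-normal matrix, and the per-patient tumor-minus-normal
log fold change — and in their column-concatenations.  This note
records the models, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
conventions.

## Data model

A cohort is a pair of genes × patients matrices over the same gene
index, aligned column-by-column through a patient ↔ (tumor sample,
normal sample) pairing.  All expression enters on a log2 scale:
microarray-style intensities as-is, count-like data through
`log2(x + 1)` at load time (`read_expression_matrix(..., log2_counts=True)`).
The fold-change view is then the additive log ratio `tumor − normal`,
identical in meaning across platforms.  Gene order is canonicalized
lexicographically on load so derived views align deterministically.

Concatenated views (`tumor+normal`, `tumor+foldchange`,
`normal+foldchange`, `tumor+normal+foldchange`) standardize each block
feature-wise (mean 0, sd 1) before joining, so that no block dominates
a penalized fit purely through scale.  Single views are left on their
native scale.

## Clustering concordance

Genes are ranked by the (unscaled) median absolute deviation across
samples; defaults keep 12,000 genes for hierarchical clustering and
6,000 for k-means, both configurable, with MAD ties broken
lexicographically by gene id for determinism.  Hierarchical clustering
is Euclidean/complete-linkage over samples; flat clustering is
best-of-25 k-means restarts (k defaults to 5, with a 2–15 sweep
available).

Dendrogram agreement is Baker's Gamma: for every leaf pair, record the
number of clusters present at the lowest cut where the pair first
co-clusters (after merge step *s* of *n* leaves that is *n − s − 1*),
and take the Spearman correlation of the two pairwise vectors.
Partition agreement is the raw Rand index (fraction of patient pairs
on which two groupings agree); the adjusted version is available via a
flag but the raw index is primary.  Patients missing a clinical label
are dropped pairwise from that comparison only.

Significance of either index is a one-sided permutation test: the
labels of exactly one side are permuted (the second view's rows before
re-clustering, or the clinical grouping), B = 1000 by default, and
p = (1 + #{null ≥ observed}) / (1 + B), which is valid and never zero.

Module-mutation groupings OR each module's member genes per patient;
with *m* modules the joint status spans 2^m categories (16 for four
driver modules).

## Survival prediction and view comparison

High-dimensional views are reduced to principal-component scores (at
most n − 1 components; components with zero singular value dropped)
before model fitting — the fit is then on a design whose width is the
cohort size, not the gene count.

The penalized model is elastic-net Cox with penalty
λ[α·Σ|β_j| + (1−α)/2·Σβ_j²], mixing α = 0.01 (nearly ridge — with PCA
scores as inputs sparsity in components is not meaningful, and a small
α keeps the problem strongly convex), λ grid-searched by
event-stratified 5-fold cross-validation.  Candidate λ values are
scored by the summed held-out deviance difference (Verweij–van
Houwelingen style): fit without the fold, then D(all data) − D(training
part).  Deviance throughout is −2 × the Breslow log partial likelihood
evaluated with the fitted linear predictor on the stated subset; no
saturated-model constant is subtracted (it is undefined for Cox
regression), so only deviance *differences* are ever interpreted.
Breslow tie handling is used everywhere because it is the simplest
deterministic convention; the generator produces continuous times, so
ties only arise in user data.

Views are compared by the **mean cross-validation error**: for fold k,
CVE_k = D(full cohort) − D(cohort minus fold k) under the model fit
without fold k, averaged over folds.  This is the deviance mass
attributable to the held-out fold; smaller is better.  By default the
PCA reduction is refit inside every fold and held-out rows are
projected with training loadings (no leakage); reducing once up front
is available via `pca_per_fold=False` and is the convention used by the
leave-pair-out consistency analysis below.  The comparison runner
repeats the CV error over 20 runs (re-randomized folds, same run seeds
for every view so runs are paired) and ranks views by median error.

The nonparametric companion is a log-rank-split random survival forest
(10,000 trees by default; studies in this repository use 500 for
tractability) whose out-of-bag error is 1 − Harrell's concordance of
the OOB ensemble predictions.

## Leave-pair-out consistency matrices

The view is PCA-reduced once on all patients.  For every unordered
patient pair (i, j), an elastic-net Cox model (α = 0.01, λ by 5-fold CV
on the full reduced design) is fit on all patients *except* i and j and
asked which held-out patient is at higher risk; over n_runs random runs
(the randomness is the CV fold draw that selects λ), M_ij is the
fraction of runs ranking i riskier than j (ties 0.5), so
M_ij + M_ji = 1.  Runs that select the same λ produce identical fits,
so pair sweeps are cached per distinct λ — a pure speed optimization
with bit-identical results.

The censoring-aware reference M_r reads the same ordering off the
observed data: a pair is *identifiable* when the smaller observed time
belongs to a death and times are untied; then the earlier death is the
higher-risk patient (M_r = 1 row-riskier orientation), and every
non-identifiable entry — including the diagonal — is 0.5.

The consistency matrix is C = 1 − |M − M_r| (1 = perfect agreement,
matching the "high = consistent" reading of the analysis; the raw
|M − M_r| is available via `absolute_difference=True`).  C is symmetric
by construction.  Per-patient summaries average C over each patient's
identifiable pairs and flag outliers below Q1 − 1.5·IQR; patients with
no identifiable pair are reported missing rather than zero.

Two limits pin the scale: if predicted risk order equals the realized
uncensored death order, mean C over identifiable pairs is exactly 1;
under label-permuted survival it sits at chance, 0.5.

## Pathway enrichment

Per-gene association with survival is a univariate Cox fit per gene
(genes standardized first; the Wald z is invariant to that).  The
solver is a vectorized Newton iteration over all genes simultaneously
with Breslow ties — fitting thousands of single-covariate models
through a general-purpose fitter would dominate the pipeline's runtime
— and is cross-checked against an independent Cox implementation in the
test suite.  The ranking statistic is z = sign(β)·Φ⁻¹(1 − p/2)
(positive = higher expression, higher hazard).

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (weight
exponent 1 on |z|), sets filtered to [10, 500] members after
intersection with the ranking.  The null permutes gene labels
(equivalently, draws random same-size sets) — the appropriate null for
a preranked list, as opposed to classic phenotype permutation.
Positive and negative scores are normalized by the mean |null ES| of
their own sign and FDR-assessed separately against the pooled null
(classic GSEA convention).  The operating threshold for reporting is
FDR ≤ 0.25.  Enrichment *direction* is reported on the survival scale:
+1 means higher set expression tracks longer survival, i.e. a negative
running-sum score on the hazard-oriented ranking.

Recurrence across cohort × view analyses counts sets passing the FDR
cut in at least `min_hits` analyses (default 5 of 18) and reports the
per-analysis signed enrichment level z = Φ⁻¹(1 − q) (q clipped to
[1e-16, 1 − 1e-16]).  Cross-cohort concordance of the selected sets
uses the overlap coefficient |A ∩ B| / min(|A|, |B|) along an FDR grid
(Jaccard via a flag); empty selections yield missing values, never
zero.

Single-sample (individualized) enrichment ranks each patient's genes by
expression and scores each set by the summed difference between the
rank-weighted in-set empirical CDF (weights rank^0.25, the standard
single-sample convention) and the unweighted out-of-set CDF.  Scores
are normalized per set by their range across samples so that per-set
Cox coefficients are scale-comparable.  A univariate Cox fit per set
then yields the per-set p-values; the normal-vs-tumor attribution
statistic is log(p_tumor/p_normal) per set, positive = "Normal
Associated", with the top 100 sets by |log ratio| reported (ties broken
by set name).

## Synthetic cohorts

The generator produces everything the analysis consumes, with known
ground truth:

* **Expression**: genes fall into `n_blocks` equicorrelated blocks
  (correlation 0.3 by default), independent across blocks and between
  the tumor and normal compartments; unit marginal variance.
* **Clusters**: patients belong to `n_clusters_truth` (default 3)
  latent clusters whose per-gene mean shifts (sd 0.5) live in a
  designated compartment, default normal.  Clinical features are copies
  of the true cluster labels, each patient's label resampled to a
  different cluster with probability 0.2.
* **Survival**: the linear predictor is effect_size × the column sum of
  the signal genes (40 genes at 0.5 by default, spread round-robin
  across blocks) read from the designated signal compartment; event
  times are Exponential(baseline_hazard·exp(lp)) with baseline 0.001
  per day (median survival near two years).  Censoring is an
  independent exponential whose rate is solved numerically (Brent) so
  the expected censored fraction hits the target (default 0.3).
  Fold-change signal is planted asymmetrically (latent shift added to
  tumor, half subtracted from normal) so neither single compartment
  carries the full contrast.
* **Mutations**: per module and patient, a mutation occurs with
  probability 0.5 and hits exactly one uniformly chosen member gene —
  mutual exclusivity within modules holds by construction.  Default
  modules avoid the survival-signal genes.

All randomness flows from one seed through named `SeedSequence`
children (expression / survival / clinical / mutation), so extending
one component never perturbs the others.

The generator targets the statistical structure the analysis assumes —
proportional hazards, block correlation, cluster/feature coupling,
module exclusivity — and deliberately not the marginal distributions of
any real platform (no library-size variation, no overdispersion, no
probe effects, no tumor-vs-normal global shift).  Passing recovery
tests therefore show that the pipeline attributes planted signal to
the right compartment under its own assumptions, not that any
particular real cohort carries such signal.

## Replicated studies and problem sizes

`pairedsurv.experiments` packages the recovery and calibration studies
run by `scripts/acceptance.py` and the acceptance tests:

* **Compartment recovery**: 20 replicates at the default conditions
  (100 pairs, 2000 genes, signal in normal), 5 CV-error runs and 5
  consistency runs per replicate, 500-tree forests, consistency PCA
  capped at 20 components.  Reported: fractions of replicates where the
  normal view beats tumor on median CV error, mean consistency, per-set
  Cox p for planted sets, and forest OOB error.
* **Clustering recovery**: 20 replicates of 80 pairs × 600 genes;
  k-means at the true k on the top-500-MAD genes per view against the
  first clinical feature, with a B = 199 permutation test.
* **Calibration**: null permutation p-values for the Rand-index test
  (60 replicates, B = 99) and Baker's-Gamma test (50 replicates,
  B = 100) KS-tested against uniform; per-gene Cox p-values on a null
  cohort (200 patients × 1000 independent genes) KS-tested and checked
  for 5% type-I error within Monte-Carlo tolerance.
* **Consistency limits**: 10 seeds × 60 patients for the perfect and
  label-permuted limits.

These sizes keep a full study under a quarter hour on one CPU while
leaving the success criteria far from their decision boundaries.

## Numerical conventions and edge cases

* Deviance and partial likelihoods subtract the running maximum of the
  linear predictor before exponentiating (stable suffix log-sum-exp).
* Constant design columns are dropped from penalized fits (logged);
  zero-variance genes and set-score rows are dropped from univariate
  Cox (logged).
* The univariate Newton solver clips steps to ±5 and coefficients to
  ±50, preventing divergence on separations; information is floored at
  1e-12.
* Fold assignments are stratified by event status; an assignment that
  leaves a training set without events is redrawn with a new seed (up
  to 5 times, warning logged).
* Zero p-values entering log ratios are clipped at the smallest
  positive double with a warning; q-values entering Φ⁻¹ are clipped to
  [1e-16, 1 − 1e-16].
* Degenerate dendrogram comparisons (two leaves: a single merge level
  on both sides) return Baker's Gamma 1 by convention.

## Known limitations

* The mean-CV-error and consistency formulas follow the documented
  conventions above; alternative deviance or difference orientations
  would shift absolute values but not view *comparisons*, which are the
  quantity of interest.
* Leave-pair-out consistency is O(n²) model fits per run; it is
  practical to a few hundred patients, beyond which the PCA component
  cap and run count are the available levers.
* Preranked GSEA's gene-label permutation null ignores inter-gene
  correlation, as in standard preranked analyses; FDRs on strongly
  block-correlated rankings are optimistic in the same way.
* The generator's exponential baseline hazard is the simplest
  proportional-hazards-consistent choice; stages only consume risk
  orderings and partial likelihoods, which are baseline-free.
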