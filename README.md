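# pairedsurv

How much survival-relevant information lives in a tumor's expression
profile, in the *paired adjacent-normal* sample from the same patient,
and in their per-gene log fold change?  `pairedsurv` is a tested
pipeline for asking that question on paired tumor/normal cohorts:

* **Clustering concordance** — cluster patients from each data view
  (top-MAD genes, Euclidean/complete-linkage trees or k-means) and
  score agreement with clinical or mutation-derived groupings via
  Baker's Gamma / the Rand index, with permutation significance.
* **Survival prediction per view** — PCA-reduced elastic-net Cox
  (penalty λ[α·Σ|β_j| + (1−α)/2·Σβ_j²], α = 0.01, λ by event-stratified
  5-fold CV) and random survival forests; views compared by the mean
  cross-validation error CVE_k = D(full) − D(minus fold k), where D is
  −2 × the Breslow log partial likelihood under the fold-k model, and
  by out-of-bag concordance error.
* **Leave-pair-out consistency matrices** — for every patient pair,
  a model fit on everyone else predicts which patient is at higher
  risk; the probability matrix M is scored against the censoring-aware
  observed ordering M_r (1 / 0 on identifiable pairs, 0.5 elsewhere) as
  C = 1 − |M − M_r|.
* **Survival-pathway enrichment** — per-gene univariate Cox z ranking →
  preranked GSEA (weighted KS running sum, gene-label permutation null,
  pos/neg-pool FDR); recurrent sets across cohort × view analyses;
  single-sample enrichment scores with per-set Cox and
  normal-vs-tumor p-value log ratios.
* **Synthetic paired cohorts** — a first-class generator with
  block-correlated genes, latent patient clusters, proportional-hazards
  survival driven by a *plantable* signal compartment (tumor / normal /
  fold change / none), tuned independent censoring, noisy clinical
  copies of the true clusters, and mutually exclusive module mutations —
  so every stage has a ground-truth recovery test.

It is aimed at statistical-genomics practitioners who have paired
tumor/normal expression (microarray log intensities or log-transformed
RNA-seq), follow-up times with right censoring, and optionally clinical
tables, GMT gene sets and binary mutation matrices.

## Worked example

Simulate a 60-patient paired cohort with survival signal planted in the
normal compartment, then ask which view predicts survival best and how
consistent its pairwise risk orderings are:

```python
import numpy as np
from pairedsurv import SimulationConfig, simulate_paired_cohort, make_feature_view
from pairedsurv.survival import compare_views
from pairedsurv.consistency import (
    pairwise_matrices, comparable_pairs, mean_consistency)

cfg = SimulationConfig(n_patients=60, n_genes=800, n_signal_genes=25,
                       signal_compartment="normal", seed=7)
cohort, surv, clinical, truth, mutations = simulate_paired_cohort(cfg)

comp = compare_views(cohort, surv, ["tumor", "normal", "foldchange"],
                     n_runs=5, seed=0)
print(comp.summary().to_string(index=False))

ident = comparable_pairs(surv)
for label in ("normal", "tumor"):
    mats = pairwise_matrices(make_feature_view(cohort, label), surv,
                             n_runs=5, seed=0, max_components=20)
    print(label, "mean consistency:",
          round(mean_consistency(mats.C, ident), 3))
```

Output:

```
      view  median_cv_error  mean_cv_error  n_runs  oob_error
    normal        69.837729      69.769725       5        NaN
foldchange        71.451152      71.387943       5        NaN
     tumor        71.820247      71.867885       5        NaN
normal mean consistency: 0.69
tumor mean consistency: 0.521
```

The normal view — where the signal was planted — has the smallest
median CV error (smaller = more held-out deviance explained), the fold
change (which contains a diluted copy of the normal compartment)
is intermediate, and the tumor view trails.  The same ordering shows up
in the pairwise consistency: the normal view's predicted risk orderings
agree with the observed survival orderings on 69% of identifiable
pairs versus 52% for tumor (0.5 is chance level).

The same analyses are scriptable from a shell: `pairedsurv simulate`,
`pairedsurv survcompare`, `pairedsurv consistency`,
`pairedsurv cluster`, `pairedsurv gsea`, `pairedsurv logratio`
(see `pairedsurv --help`).

## Documentation

`docs/methods.md` describes the models and conventions in full: the
deviance and CV-error definitions, the consistency-matrix construction,
the enrichment statistics, what the synthetic generator does and does
not emulate, and the package's numerical edge-case handling.
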