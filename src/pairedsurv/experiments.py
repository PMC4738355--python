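"""Replicated recovery and calibration studies on synthetic cohorts.

These runners wire the full pipeline together under planted ground
truth: they generate paired cohorts with a known signal compartment and
ask each analysis stage whether it attributes the survival signal to
the right place (view comparison by CV error and forest OOB error,
pairwise consistency, per-set Cox on single-sample enrichment,
clustering concordance), or whether its p-values are calibrated when
nothing is planted.  Every study is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .cluster import (
    kmeans_partition,
    permutation_test_partitions,
    permutation_test_trees,
    rand_index,
    select_top_mad_genes,
)
from .consistency import (
    comparable_pairs,
    consistency,
    mean_consistency,
    probability_matrix,
    probability_matrix_from_scores,
    reference_matrix,
)
from .enrichment import (
    geneset_survival_pvalues,
    single_sample_scores,
    univariate_cox_from_matrix,
)
from .io import FeatureView, SurvivalTable, expression_view, make_feature_view
from .simulate import SimulationConfig, make_gene_set_collection, simulate_paired_cohort
from .survival import fit_random_survival_forest, mean_cv_error


def _rep_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def compartment_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    n_runs: int = 5,
    n_trees: int = 500,
    max_components: int = 20,
    include_forest: bool = True,
    views: tuple[str, str] = ("normal", "tumor"),
) -> pd.DataFrame:
    """Can each stage tell which compartment carries the planted signal?

    Per replicate the study simulates a paired cohort (default
    conditions: 100 pairs, 2000 genes, 40 signal genes at effect 0.5 in
    the normal compartment, 30% censoring) and records, for the signal
    view and the contrast view: the median mean-CV-error over ``n_runs``
    runs, the mean leave-pair-out consistency over identifiable pairs,
    the fraction of planted gene sets whose per-set Cox p is smaller in
    the signal view, and (optionally) the survival-forest OOB error.
    """
    base = base_config or SimulationConfig()
    rows = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_replicates)):
        cfg = replace(base, seed=rep_seed)
        cohort, surv, _, truth, _ = simulate_paired_cohort(cfg)
        fv = {label: make_feature_view(cohort, label) for label in views}
        row: dict = {"replicate": rep, "seed": rep_seed}

        for label in views:
            errs = [mean_cv_error(fv[label], surv, seed=(rep_seed + r) % (2**31 - 1))
                    for r in range(n_runs)]
            row[f"cve_{label}"] = float(np.median(errs))

        M_r = reference_matrix(surv)
        ident = comparable_pairs(surv)
        for label in views:
            M = probability_matrix(fv[label], surv, n_runs=n_runs, seed=rep_seed,
                                   max_components=max_components)
            row[f"mean_consistency_{label}"] = mean_consistency(
                consistency(M, M_r), ident)

        sets, planted = make_gene_set_collection(
            cfg.gene_ids, truth.signal_genes, n_planted=5, n_null=20,
            set_size=20, seed=rep_seed)
        pvals = {}
        for label in views:
            scores = single_sample_scores(expression_view(cohort, label), sets)
            pvals[label] = geneset_survival_pvalues(scores, surv)["p"]
        a, b = views
        row["planted_sets_signal_smaller_p"] = float(
            np.mean(pvals[a].loc[planted].to_numpy()
                    < pvals[b].loc[planted].to_numpy()))

        if include_forest:
            for label in views:
                _, oob = fit_random_survival_forest(
                    fv[label], surv, n_trees=n_trees, seed=rep_seed)
                row[f"oob_{label}"] = oob
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_fractions(study: pd.DataFrame,
                       signal: str = "normal",
                       contrast: str = "tumor") -> dict[str, float]:
    """Per-criterion success fractions of a compartment recovery study."""
    out = {
        "cve_recovery_fraction": float(
            (study[f"cve_{signal}"] < study[f"cve_{contrast}"]).mean()),
        "consistency_recovery_fraction": float(
            (study[f"mean_consistency_{signal}"]
             > study[f"mean_consistency_{contrast}"]).mean()),
        "pathway_recovery_fraction": float(
            (study["planted_sets_signal_smaller_p"] > 0.5).mean()),
    }
    if f"oob_{signal}" in study:
        out["oob_recovery_fraction"] = float(
            (study[f"oob_{signal}"] < study[f"oob_{contrast}"]).mean())
    return out


def clustering_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    n_top_genes: int = 500,
    B: int = 199,
) -> pd.DataFrame:
    """Do normal-view clusters track clinical features better than tumor?

    Clinical features are noisy copies of latent clusters planted in the
    normal compartment; per replicate, k-means (k = true cluster count)
    on the top-MAD genes of each view is compared with the first
    clinical feature by Rand index, plus a permutation p-value for the
    normal-view association.
    """
    base = base_config or SimulationConfig(
        n_patients=80, n_genes=600, n_blocks=12, n_signal_genes=20)
    rows = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_replicates)):
        cfg = replace(base, seed=rep_seed)
        cohort, _, clinical, truth, _ = simulate_paired_cohort(cfg)
        feature = clinical.labels(clinical.feature_names[0])
        k = cfg.n_clusters_truth
        row = {"replicate": rep, "seed": rep_seed}
        parts = {}
        for label in ("normal", "tumor"):
            expr = select_top_mad_genes(expression_view(cohort, label),
                                        min(n_top_genes, cfg.n_genes))
            view = FeatureView(label, list(expr.sample_ids), list(expr.gene_ids),
                               expr.values.T)
            parts[label] = kmeans_partition(view, k, seed=rep_seed)
            row[f"rand_{label}"] = rand_index(parts[label], feature)
        test = permutation_test_partitions(parts["normal"], feature, B=B,
                                           seed=rep_seed)
        row["normal_perm_p"] = test.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def partition_pvalue_calibration(
    n_replicates: int = 60,
    seed: int = 0,
    n_patients: int = 50,
    B: int = 99,
) -> dict[str, float | np.ndarray]:
    """Null permutation p-values for Rand-index tests: KS against uniform."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    from .cluster import Partition
    ids = [f"P{i:04d}" for i in range(n_patients)]
    for i in range(n_replicates):
        a = rng.integers(1, 4, n_patients)
        b = rng.integers(1, 4, n_patients)
        pa = Partition(ids, _relabel(a))
        pvals[i] = permutation_test_partitions(
            pa, pd.Series(b, index=ids), B=B,
            seed=int(rng.integers(0, 2**31 - 1))).p_value
    ks = kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue)}


def tree_pvalue_calibration(
    n_replicates: int = 50,
    seed: int = 0,
    n_patients: int = 30,
    n_genes: int = 20,
    B: int = 100,
) -> dict[str, float | np.ndarray]:
    """Null permutation p-values for Baker's Gamma tests on noise views."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    ids = [f"P{i:04d}" for i in range(n_patients)]
    genes = [f"g{i:04d}" for i in range(n_genes)]
    for i in range(n_replicates):
        v1 = FeatureView("tumor", ids, genes, rng.normal(size=(n_patients, n_genes)))
        v2 = FeatureView("normal", ids, genes, rng.normal(size=(n_patients, n_genes)))
        pvals[i] = permutation_test_trees(
            v1, v2, B=B, seed=int(rng.integers(0, 2**31 - 1))).p_value
    ks = kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue)}


def cox_pvalue_calibration(
    seed: int = 0,
    n_patients: int = 200,
    n_genes: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float | np.ndarray]:
    """Per-gene Cox p-values under a null cohort (no planted signal,
    independent genes): type-I rate at ``alpha`` and KS against uniform."""
    cfg = SimulationConfig(
        n_patients=n_patients, n_genes=n_genes, n_blocks=n_genes,
        block_correlation=0.0, signal_compartment="none", n_signal_genes=0,
        cluster_separation=0.0, censoring_rate_target=0.3, seed=seed)
    cohort, surv, *_ = simulate_paired_cohort(cfg)
    expr = expression_view(cohort, "normal")
    ranking = univariate_cox_from_matrix(expr.values, expr.gene_ids,
                                         surv.reorder(expr.sample_ids))
    p = ranking.table["p"].to_numpy()
    ks = kstest(p, "uniform")
    return {
        "pvalues": p,
        "type1_rate": float((p < alpha).mean()),
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / len(p))),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def consistency_limit_study(
    seed: int = 0,
    n_patients: int = 60,
    n_seeds: int = 10,
) -> dict[str, float]:
    """Consistency-matrix limits: exact agreement under perfect
    uncensored predictions; chance-level (~0.5) under label-permuted
    survival."""
    perfect = []
    permuted = []
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        lp = rng.normal(size=n_patients)
        # perfect prediction: observed order realizes the predicted order
        surv = SurvivalTable([f"P{i:04d}" for i in range(n_patients)],
                             1.0 / np.exp(lp), np.ones(n_patients, dtype=int))
        M = probability_matrix_from_scores(lp)
        perfect.append(mean_consistency(consistency(M, reference_matrix(surv)),
                                        comparable_pairs(surv)))
        perm = rng.permutation(n_patients)
        shuffled = SurvivalTable(surv.patient_ids, surv.time[perm],
                                 surv.event[perm])
        permuted.append(mean_consistency(
            consistency(M, reference_matrix(shuffled)),
            comparable_pairs(shuffled)))
    return {
        "perfect_mean_consistency": float(np.mean(perfect)),
        "permuted_mean_consistency": float(np.mean(permuted)),
    }


def _relabel(labels: np.ndarray) -> np.ndarray:
    remap: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out
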