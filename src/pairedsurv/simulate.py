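"""Synthetic paired tumor/normal cohorts with plantable survival signal.

The generator produces everything the analysis consumes — paired
expression matrices, a right-censored survival table, clinical
groupings, mutually exclusive module mutations, and gene sets — with
known ground truth, so every downstream stage has a recovery test:

* genes fall into correlated blocks (equicorrelated Gaussian within a
  block, independent across blocks);
* patients belong to latent clusters whose mean shifts live in a
  designated compartment (default: normal), and clinical features are
  noisy copies of the true cluster labels;
* survival follows an exponential proportional-hazards model whose
  linear predictor is a weighted sum of *signal genes* read from a
  designated compartment (tumor, normal, fold change, or none);
* censoring is an independent exponential time whose rate is solved
  numerically to hit a target censored fraction.

The generator targets the statistical structure the analysis assumes
(proportional hazards, block correlation, cluster/feature coupling),
not the marginal distributions of any real platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, PairedCohort, SurvivalTable

COMPARTMENTS = ("tumor", "normal", "foldchange", "none")


@dataclass
class SimulationConfig:
    """All knobs of the paired-cohort generator; ``seed`` fully determines output.

    ``effect_size`` is the per-gene log-hazard coefficient applied to
    every signal gene.  ``baseline_hazard`` is per day; the default
    puts median survival near two years, a typical cohort time scale.
    """

    n_patients: int = 100
    n_genes: int = 2000
    n_blocks: int = 20
    block_correlation: float = 0.3
    signal_compartment: str = "normal"
    n_signal_genes: int = 40
    effect_size: float = 0.5
    baseline_hazard: float = 0.001
    censoring_rate_target: float = 0.3
    n_clusters_truth: int = 3
    cluster_compartment: str = "normal"
    cluster_separation: float = 0.5
    n_clinical_features: int = 5
    clinical_noise: float = 0.2
    mutation_modules: list[list[str]] | None = None
    n_mutation_modules: int = 4
    module_size: int = 3
    module_mutation_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_compartment not in COMPARTMENTS:
            raise ValueError(f"signal_compartment must be one of {COMPARTMENTS}")
        if self.cluster_compartment not in ("tumor", "normal", "both"):
            raise ValueError("cluster_compartment must be tumor, normal or both")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if not 0.0 <= self.censoring_rate_target < 1.0:
            raise ValueError("censoring_rate_target must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_blocks < 1 or self.n_patients < 2 or self.n_genes < 1:
            raise ValueError("n_blocks, n_patients, n_genes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests downstream."""

    signal_genes: list[str]
    linear_predictor: np.ndarray  # per patient, exact signal-submatrix product
    cluster_labels: np.ndarray  # true latent cluster per patient, 1..K
    module_mutated: pd.DataFrame  # patients x modules binary
    signal_compartment: str


def _block_correlated(rng: np.random.Generator, n_genes: int, n_patients: int,
                      block_of: np.ndarray, n_blocks: int, rho: float) -> np.ndarray:
    """Equicorrelated-within-block Gaussian noise, unit marginal variance."""
    z = rng.standard_normal((n_blocks, n_patients))
    eps = rng.standard_normal((n_genes, n_patients))
    return np.sqrt(rho) * z[block_of, :] + np.sqrt(1.0 - rho) * eps


def survival_from_linear_predictor(
    lp: np.ndarray,
    baseline_hazard: float,
    censoring_rate_target: float,
    seed: int | np.random.Generator,
    patient_ids: list[str] | None = None,
) -> SurvivalTable:
    """Exponential proportional-hazards event times with tuned censoring.

    Event times are Exponential(rate = baseline_hazard * exp(lp)); a
    uniform shift of the linear predictor therefore rescales every
    event time.  The censoring time is an independent Exponential whose
    rate is solved (Brent root find) so the *expected* censored
    fraction equals the target.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor must be finite")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = lp.shape[0]
    rates = baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rates)
    if censoring_rate_target <= 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        # E[censored fraction] = mean_i c / (c + rate_i), increasing in c
        def frac(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + rates))) - censoring_rate_target

        lo, hi = np.log(rates.min()) - 30.0, np.log(rates.max()) + 30.0
        c_rate = np.exp(brentq(frac, lo, hi))
        C = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]
    return SurvivalTable(patient_ids, time, event)


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[PairedCohort, SurvivalTable, ClinicalTable, GroundTruth, pd.DataFrame]:
    """Generate one paired cohort plus survival, clinical, truth and mutations.

    Randomness is split from ``config.seed`` through named
    ``SeedSequence`` children (expression / survival / clinical /
    mutation), so adding draws to one component never perturbs the
    others.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_expr, rng_surv, rng_clin, rng_mut = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    genes = cfg.gene_ids
    patients = [f"P{i:04d}" for i in range(cfg.n_patients)]
    block_of = np.arange(cfg.n_genes) % cfg.n_blocks

    tumor = _block_correlated(rng_expr, cfg.n_genes, cfg.n_patients, block_of,
                              cfg.n_blocks, cfg.block_correlation)
    normal = _block_correlated(rng_expr, cfg.n_genes, cfg.n_patients, block_of,
                               cfg.n_blocks, cfg.block_correlation)

    # latent patient clusters; mean shifts live in the designated compartment
    clusters = 1 + (rng_expr.permutation(cfg.n_patients) % cfg.n_clusters_truth)
    delta = rng_expr.normal(0.0, cfg.cluster_separation,
                            size=(cfg.n_genes, cfg.n_clusters_truth))
    shift = delta[:, clusters - 1]
    if cfg.cluster_compartment in ("normal", "both"):
        normal = normal + shift
    if cfg.cluster_compartment in ("tumor", "both"):
        tumor = tumor + shift

    sig_idx = np.arange(cfg.n_signal_genes)
    if cfg.signal_compartment == "foldchange":
        # plant an asymmetric latent shift so neither single compartment
        # carries the full contrast signal
        latent = rng_expr.standard_normal((cfg.n_signal_genes, cfg.n_patients))
        tumor[sig_idx, :] += latent
        normal[sig_idx, :] -= 0.5 * latent

    if cfg.signal_compartment == "tumor":
        signal_matrix = tumor[sig_idx, :]
    elif cfg.signal_compartment == "normal":
        signal_matrix = normal[sig_idx, :]
    elif cfg.signal_compartment == "foldchange":
        signal_matrix = tumor[sig_idx, :] - normal[sig_idx, :]
    else:
        signal_matrix = np.zeros((0, cfg.n_patients))

    beta = np.full(signal_matrix.shape[0], cfg.effect_size)
    lp = beta @ signal_matrix if signal_matrix.size else np.zeros(cfg.n_patients)

    surv = survival_from_linear_predictor(
        lp, cfg.baseline_hazard, cfg.censoring_rate_target, rng_surv, patients
    )

    # clinical features: noisy copies of the true cluster labels
    feats = {}
    labels = np.arange(1, cfg.n_clusters_truth + 1)
    for f in range(cfg.n_clinical_features):
        noisy = clusters.copy()
        flip = rng_clin.random(cfg.n_patients) < cfg.clinical_noise
        for i in np.flatnonzero(flip):
            others = labels[labels != clusters[i]]
            noisy[i] = rng_clin.choice(others) if others.size else clusters[i]
        feats[f"feature_{f:02d}"] = noisy
    clinical = ClinicalTable(pd.DataFrame(feats, index=pd.Index(patients, name="patient_id")))

    # mutually exclusive module mutations: at most one member gene per patient
    modules = cfg.mutation_modules
    if modules is None:
        start = cfg.n_signal_genes  # keep modules off the survival-signal genes
        modules = [
            genes[start + m * cfg.module_size: start + (m + 1) * cfg.module_size]
            for m in range(cfg.n_mutation_modules)
        ]
    for m, members in enumerate(modules):
        if not members:
            raise ValueError(f"mutation module {m} is empty")
        unknown = [g for g in members if g not in genes]
        if unknown:
            raise ValueError(f"module {m} contains unknown genes: {unknown}")
    mut = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=patients)
    module_hit = np.zeros((cfg.n_patients, len(modules)), dtype=int)
    for m, members in enumerate(modules):
        hit = rng_mut.random(cfg.n_patients) < cfg.module_mutation_prob
        which = rng_mut.integers(0, len(members), size=cfg.n_patients)
        for i in np.flatnonzero(hit):
            mut.loc[members[which[i]], patients[i]] = 1
            module_hit[i, m] = 1
    module_df = pd.DataFrame(
        module_hit, index=patients,
        columns=[f"module_{m}" for m in range(len(modules))],
    )

    tumor_ids = [f"{p}-T" for p in patients]
    normal_ids = [f"{p}-N" for p in patients]
    cohort = PairedCohort(
        tumor=ExpressionMatrix(pd.DataFrame(tumor, index=genes, columns=tumor_ids)),
        normal=ExpressionMatrix(pd.DataFrame(normal, index=genes, columns=normal_ids)),
        patient_ids=patients,
        pairing={p: (t, n) for p, t, n in zip(patients, tumor_ids, normal_ids)},
    )
    truth = GroundTruth(
        signal_genes=[genes[i] for i in sig_idx] if cfg.signal_compartment != "none" else [],
        linear_predictor=np.asarray(lp, dtype=float),
        cluster_labels=clusters,
        module_mutated=module_df,
        signal_compartment=cfg.signal_compartment,
    )
    return cohort, surv, clinical, truth, mut


def make_gene_set_collection(
    gene_ids: list[str],
    signal_genes: list[str],
    n_planted: int = 5,
    n_null: int = 20,
    set_size: int = 20,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Gene sets for enrichment recovery: planted sets drawn from the
    signal genes, null sets from the remainder.

    Returns the collection and the list of planted set names.
    """
    rng = np.random.default_rng(seed)
    non_signal = [g for g in gene_ids if g not in set(signal_genes)]
    if set_size > len(non_signal):
        raise ValueError("set_size exceeds available non-signal genes")
    sets: dict[str, list[str]] = {}
    planted_names = []
    k_sig = min(set_size, len(signal_genes))
    for i in range(n_planted):
        members = list(rng.choice(signal_genes, size=k_sig, replace=False))
        if k_sig < set_size:
            members += list(rng.choice(non_signal, size=set_size - k_sig, replace=False))
        name = f"PLANTED_{i:02d}"
        sets[name] = members
        planted_names.append(name)
    for i in range(n_null):
        sets[f"NULL_{i:02d}"] = list(rng.choice(non_signal, size=set_size, replace=False))
    return sets, planted_names
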