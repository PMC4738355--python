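"""Patient clustering per data view and concordance with clinical groupings.

Hierarchical clustering uses Euclidean distance with complete linkage on
the most-varying genes (ranked by median absolute deviation); dendrogram
similarity is Baker's Gamma, the Spearman correlation over all leaf
pairs of the number of clusters present at the lowest cut where the
pair first co-clusters.  Flat clustering is k-means on the top-MAD
genes; partition similarity is the Rand index.  Significance of either
index is calibrated by permuting the labels of one side and recomputing
(one-sided: similarity at least as large as observed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix, FeatureView

DEFAULT_N_GENES_HIER = 12_000
DEFAULT_N_GENES_KMEANS = 6_000
DEFAULT_K = 5
DEFAULT_PERMUTATIONS = 1_000


@dataclass
class Partition:
    """Flat cluster assignment; labels are 1..k with no empty cluster."""

    patient_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.patient_ids),):
            raise ValueError("one label per patient required")
        present = np.unique(self.labels)
        k = present.max(initial=0)
        if not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError("labels must cover 1..k with every cluster nonempty")

    @property
    def k(self) -> int:
        return int(self.labels.max())


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples (scipy linkage encoding)."""

    leaf_ids: list[str]
    Z: np.ndarray  # (n-1) x 4 scipy linkage matrix

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float

    @property
    def B(self) -> int:
        return len(self.null)


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median absolute deviation, unscaled: median(|x - median(x)|)."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def select_top_mad_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with largest MAD across samples.

    Ties are broken lexicographically by gene id so the selection is
    deterministic; original gene order is preserved in the output.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > expr.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {expr.shape[0]}")
    scores = mad(expr.values, axis=1)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], expr.gene_ids[i]))
    keep = sorted(order[:n])
    return ExpressionMatrix(expr.df.iloc[keep])


def hierarchical_cluster(view: FeatureView) -> Dendrogram:
    """Agglomerative complete-linkage tree on Euclidean distances between samples."""
    if view.n_patients < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = linkage(view.X, method="complete", metric="euclidean")
    return Dendrogram(leaf_ids=list(view.patient_ids), Z=Z)


def _pair_merge_clusters(dend: Dendrogram) -> dict[tuple[str, str], int]:
    """For every leaf pair, the number of clusters present at the lowest
    cut where the pair first co-clusters.

    After merge step s (0-based) the tree has n - s - 1 clusters; a pair
    joined at step s therefore first co-clusters at the n - s - 1 cut.
    """
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    out: dict[tuple[str, str], int] = {}
    ids = dend.leaf_ids
    for s, (a, b, _h, _cnt) in enumerate(dend.Z):
        ga, gb = members.pop(int(a)), members.pop(int(b))
        level = n - s - 1
        for i in ga:
            for j in gb:
                key = (ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i])
                out[key] = level
        members[n + s] = ga + gb
    return out


def bakers_gamma(d1: Dendrogram, d2: Dendrogram) -> float:
    """Baker's Gamma: Spearman correlation of pairwise first-co-clustering levels."""
    if set(d1.leaf_ids) != set(d2.leaf_ids):
        raise ValueError("dendrograms must share the same leaf set")
    m1 = _pair_merge_clusters(d1)
    m2 = _pair_merge_clusters(d2)
    keys = sorted(m1)
    v1 = np.array([m1[k] for k in keys], dtype=float)
    v2 = np.array([m2[k] for k in keys], dtype=float)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        # degenerate: all pairs merge at one level (n = 2); treat as perfect
        return 1.0
    rho = spearmanr(v1, v2).statistic
    return float(rho)


def _permutation_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + np.sum(null >= observed)) / (1.0 + len(null))


def permutation_test_trees(
    view1: FeatureView,
    view2: FeatureView,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Significance of Baker's Gamma between two views' dendrograms.

    The null permutes the sample labels of ``view2`` (rows shuffled
    relative to ids) and re-clusters; one-sided p for similarity at
    least as large as observed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if set(view1.patient_ids) != set(view2.patient_ids):
        raise ValueError("views must share the same samples")
    rng = np.random.default_rng(seed)
    d1 = hierarchical_cluster(view1)
    observed = bakers_gamma(d1, hierarchical_cluster(view2))
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(view2.n_patients)
        shuffled = FeatureView(
            label=view2.label,
            patient_ids=view2.patient_ids,
            feature_names=view2.feature_names,
            X=view2.X[perm],
        )
        null[b] = bakers_gamma(d1, hierarchical_cluster(shuffled))
    return PermutationResult(observed, null, _permutation_p(observed, null))


def kmeans_partition(
    view: FeatureView, k: int, seed: int = 0, n_restarts: int = 25
) -> Partition:
    """Best-of-restarts k-means on the view; deterministic given seed."""
    if not 2 <= k <= view.n_patients:
        raise ValueError(f"k={k} out of range [2, {view.n_patients}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(view.X)
    # relabel to 1..k' over occupied clusters, in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    remap = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return Partition(patient_ids=list(view.patient_ids), labels=out)


def kmeans_sweep(
    view: FeatureView, ks: range | list[int] = range(2, 16), seed: int = 0,
    n_restarts: int = 25,
) -> dict[int, Partition]:
    """k-means partitions for a range of k (default 2-15)."""
    return {k: kmeans_partition(view, k, seed=seed, n_restarts=n_restarts)
            for k in ks}


def _align_partitions(
    p1: Partition, labels2: pd.Series | Partition
) -> tuple[np.ndarray, np.ndarray]:
    """Common-patient label vectors, dropping patients with missing labels."""
    if isinstance(labels2, Partition):
        s2 = pd.Series(labels2.labels, index=labels2.patient_ids)
    else:
        s2 = labels2
    s1 = pd.Series(p1.labels, index=p1.patient_ids)
    common = [p for p in p1.patient_ids if p in s2.index and pd.notna(s2[p])]
    if len(common) < 2:
        raise ValueError("need at least 2 shared labelled patients")
    return s1[common].to_numpy(), s2[common].to_numpy()


def _rand_from_labels(a: np.ndarray, b: np.ndarray, adjusted: bool) -> float:
    if adjusted:
        return float(adjusted_rand_score(a, b))
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree) / (n * (n - 1) // 2)


def rand_index(
    p1: Partition, p2: Partition | pd.Series, adjusted: bool = False
) -> float:
    """Rand index between a partition and another partition or labelling.

    Raw Rand by default: the fraction of patient pairs on which the two
    groupings agree (co-clustered in both or separated in both).
    Patients missing a label on either side are dropped pairwise.
    ``adjusted=True`` gives the chance-corrected version.
    """
    a, b = _align_partitions(p1, p2)
    return _rand_from_labels(a, b, adjusted)


def permutation_test_partitions(
    p1: Partition,
    grouping: pd.Series | Partition,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    adjusted: bool = False,
) -> PermutationResult:
    """Significance of the Rand index against label-permuted groupings."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = _align_partitions(p1, grouping)
    observed = _rand_from_labels(a, b, adjusted)
    null = np.empty(B)
    for i in range(B):
        null[i] = _rand_from_labels(a, rng.permutation(b), adjusted)
    return PermutationResult(observed, null, _permutation_p(observed, null))


def _canon(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k by first appearance."""
    remap: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out


def module_mutation_partition(
    mutations: pd.DataFrame, modules: dict[str, list[str]]
) -> tuple[Partition, pd.Series]:
    """Group patients by joint module mutation status.

    A module counts as mutated in a patient if any member gene is
    mutated; with m modules each patient lands in one of 2^m binary
    categories.  Returns the partition (labels 1..k over occupied
    categories) and the per-patient binary code strings (e.g. "0100").
    """
    patients = list(mutations.columns)
    codes = []
    for name, members in modules.items():
        if not members:
            raise ValueError(f"module {name!r} is empty")
        missing = [g for g in members if g not in mutations.index]
        if missing:
            raise ValueError(f"module {name!r} genes absent from matrix: {missing}")
    for p in patients:
        bits = "".join(
            "1" if mutations.loc[members, p].any() else "0"
            for members in modules.values()
        )
        codes.append(bits)
    code_series = pd.Series(codes, index=patients)
    labels = _canon(np.array(codes))
    return Partition(patients, labels), code_series
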