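"""Shared test-data builders and independent brute-force oracles.

The oracles deliberately re-derive each statistic from its definition
(pair enumeration, running-sum walks, direct partial-likelihood sums)
without touching the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pairedsurv.io import ExpressionMatrix, FeatureView

def make_view(X: np.ndarray, label: str = "tumor") -> FeatureView:
    n, p = X.shape
    return FeatureView(
        label=label,
        patient_ids=[f"P{i:04d}" for i in range(n)],
        feature_names=[f"g{j:05d}" for j in range(p)],
        X=np.asarray(X, dtype=float),
    )


def make_expr(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    g, s = values.shape
    genes = genes or [f"g{i:05d}" for i in range(g)]
    samples = samples or [f"S{i:03d}" for i in range(s)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# oracles


def rand_index_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Rand index by explicit enumeration of every item pair."""
    n = len(a)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total


def pair_merge_level_oracle(Z: np.ndarray, leaf_ids: list[str]) -> dict:
    """For each leaf pair, the cluster count at its first co-clustering,
    found by scanning flat cuts at every cluster number."""
    from scipy.cluster.hierarchy import cut_tree

    n = len(leaf_ids)
    cuts = {k: cut_tree(Z, n_clusters=k).ravel() for k in range(1, n + 1)}
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            # largest k at which the pair shares a flat cluster
            level = max(k for k in range(1, n + 1) if cuts[k][i] == cuts[k][j])
            key = tuple(sorted((leaf_ids[i], leaf_ids[j])))
            out[key] = level
    return out


def breslow_loglik_oracle(lp, time, event) -> float:
    """Cox log partial likelihood by direct summation (Breslow ties)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [np.exp(lp[j]) for j in range(len(time)) if time[j] >= time[i]]
            ll += lp[i] - np.log(sum(risk))
    return ll


def gsea_es_oracle(z_ordered, in_set_mask, weight=1.0) -> float:
    """Enrichment score by walking the full ranking position by position."""
    z_ordered = np.asarray(z_ordered, float)
    mask = np.asarray(in_set_mask, bool)
    N = len(z_ordered)
    k = mask.sum()
    nr = np.sum(np.abs(z_ordered[mask]) ** weight)
    running = 0.0
    best = 0.0
    for i in range(N):
        if mask[i]:
            running += np.abs(z_ordered[i]) ** weight / nr
        else:
            running -= 1.0 / (N - k)
        if abs(running) > abs(best):
            best = running
    return best


def ssgsea_score_oracle(expr_col, in_set_mask, weight=0.25) -> float:
    """Single-sample score by walking the ranking and summing CDF gaps."""
    expr_col = np.asarray(expr_col, float)
    mask = np.asarray(in_set_mask, bool)
    N = len(expr_col)
    order = np.argsort(-expr_col, kind="stable")
    rank_value = np.arange(N, 0, -1, dtype=float)
    m = mask[order]
    w = np.where(m, rank_value**weight, 0.0)
    k = m.sum()
    total = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in range(N):
        if m[i]:
            cum_in += w[i] / w.sum()
        else:
            cum_out += 1.0 / (N - k)
        total += cum_in - cum_out
    return total
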