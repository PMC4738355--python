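"""Survival-pathway enrichment per cohort and data view.

Per-gene association with survival is a univariate Cox regression; the
signed Wald z statistic (positive = higher expression, higher hazard)
ranks the genes for preranked GSEA with the weighted Kolmogorov-Smirnov
running-sum statistic and a gene-label permutation null.  Enrichment
direction is reported on the survival scale: positive direction means
higher expression of the set's genes associates with *longer* survival
(a negative running-sum enrichment score on the hazard-oriented
ranking).  Recurrently enriched sets are tallied across cohort x view
analyses at an FDR threshold, and cross-cohort agreement is the overlap
coefficient of the selected sets along an FDR grid.

Single-sample (individualized) enrichment converts each patient's
expression profile into per-gene-set scores via the rank-weighted
running-sum statistic; a univariate Cox regression on each set's score
vector then asks which pathways are most predictive of survival in a
given compartment.

The per-gene Cox fits use a dedicated vectorized Newton solver (all
genes solved simultaneously, Breslow ties) because fitting thousands of
single-covariate models through a general-purpose fitter dominates the
pipeline's runtime; the solver is cross-checked against an independent
Cox implementation in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, FeatureView, SurvivalTable

logger = logging.getLogger(__name__)

Q_CLIP = 1e-16


# ---------------------------------------------------------------------------
# univariate Cox


def _newton_univariate_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 25,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row single-covariate Cox fits (Breslow ties), all rows at once.

    X is genes x patients, columns standardized by the caller.  Returns
    (beta, se).
    """
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = event[order].astype(bool)
    Xs = X[:, order]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    G = X.shape[0]
    beta = np.zeros(G)
    for _ in range(max_iter):
        eta = beta[:, None] * Xs
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        s1 = np.cumsum((Xs * w)[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        s2 = np.cumsum((Xs**2 * w)[:, ::-1], axis=1)[:, ::-1][:, first_idx]
        mu = s1 / s0
        score = np.sum((Xs - mu)[:, e_s], axis=1)
        info = np.sum((s2 / s0 - mu**2)[:, e_s], axis=1)
        info = np.maximum(info, 1e-12)
        step = np.clip(score / info, -5.0, 5.0)
        beta = np.clip(beta + step, -50.0, 50.0)
        if np.max(np.abs(step)) < tol:
            break
    se = 1.0 / np.sqrt(info)
    return beta, se


@dataclass
class GeneRanking:
    """Signed per-gene survival association: z = sign(coef) * Phi^-1(1 - p/2)."""

    table: pd.DataFrame  # index gene_id; columns coef, z, p

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def z(self) -> pd.Series:
        return self.table["z"]

    def ordered(self) -> pd.Series:
        """z sorted descending (most hazardous first), ties by gene id."""
        df = self.table.sort_index().sort_values("z", ascending=False, kind="stable")
        return df["z"]


def univariate_cox_from_matrix(
    values: np.ndarray, row_ids: list[str], surv: SurvivalTable
) -> GeneRanking:
    """Univariate Cox per row of a rows x patients matrix."""
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d zero-variance rows", int((~keep).sum()))
    if not keep.any():
        raise ValueError("no varying rows to rank")
    Xz = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    beta, se = _newton_univariate_cox(Xz, surv.time, surv.event)
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"coef": beta, "z": z, "p": p},
        index=pd.Index([r for r, k in zip(row_ids, keep) if k], name="id"),
    )
    return GeneRanking(table)


def univariate_cox_ranking(
    view: FeatureView | ExpressionMatrix, surv: SurvivalTable
) -> GeneRanking:
    """Per-gene univariate Cox z ranking for a view or expression matrix.

    Each gene is standardized before fitting (the Wald z is invariant
    to affine rescaling of a single covariate, so this only aids the
    numerics).
    """
    if isinstance(view, ExpressionMatrix):
        values, ids = view.values, view.gene_ids
        surv = surv.reorder(view.sample_ids)
    else:
        values, ids = view.X.T, view.feature_names
        surv = surv.reorder(view.patient_ids)
    return univariate_cox_from_matrix(values, ids, surv)


# ---------------------------------------------------------------------------
# preranked GSEA


def enrichment_score(z_ordered: np.ndarray, hit_positions: np.ndarray,
                     weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one gene set.

    ``z_ordered`` is the ranking metric sorted descending;
    ``hit_positions`` are 0-based positions of set members in that
    order.  Hits advance by |z|^weight (normalized), misses retreat by
    1/(N - k); the ES is the running sum's largest absolute excursion,
    signed.
    """
    N = len(z_ordered)
    pos = np.sort(np.asarray(hit_positions, dtype=int))
    k = len(pos)
    if k == 0 or k >= N:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    w = np.abs(z_ordered[pos]) ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    hit_cum = np.cumsum(w) / total
    miss_unit = 1.0 / (N - k)
    # running sum is piecewise linear; extremes occur at hit positions:
    # just after hit m, and just before hit m
    after = hit_cum - (pos + 1 - np.arange(1, k + 1)) * miss_unit
    before = np.concatenate(([0.0], hit_cum[:-1])) - (pos - np.arange(k)) * miss_unit
    hi = after.max()
    lo = before.min()
    return float(hi if hi >= -lo else lo)


def _null_es(
    z_ordered: np.ndarray, size: int, n_perm: int, rng: np.random.Generator,
    weight: float,
) -> np.ndarray:
    N = len(z_ordered)
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = rng.choice(N, size=size, replace=False)
        out[b] = enrichment_score(z_ordered, pos, weight)
    return out


def gsea_preranked(
    ranking: GeneRanking,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    weight: float = 1.0,
    cohort: str = "",
    view: str = "",
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Sets are intersected with the ranked genes and filtered to
    [min_size, max_size].  The null permutes gene labels (equivalently,
    draws random same-size sets from the ranking).  Positive and
    negative enrichment scores are normalized by the mean |null ES| of
    their own sign and FDR-assessed separately against the pooled null
    (classic GSEA convention).  Direction is reported on the survival
    scale: +1 when higher set expression tracks longer survival
    (negative ES on the hazard-oriented ranking).

    Returns one row per retained set: size, es, nes, direction, p, q,
    cohort, view.
    """
    z_series = ranking.ordered()
    z_ordered = z_series.to_numpy()
    gene_pos = {g: i for i, g in enumerate(z_series.index)}
    rng = np.random.default_rng(seed)

    kept: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        if min_size <= len(pos) <= max_size and len(pos) < len(z_ordered):
            kept[name] = pos
    if not kept:
        raise ValueError("no gene set survives size filtering")

    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    all_null_nes = []
    for name, pos in kept.items():
        k = len(pos)
        if k not in null_by_size:
            null_by_size[k] = _null_es(z_ordered, k, n_perm, rng, weight)
        es = enrichment_score(z_ordered, pos, weight)
        null = null_by_size[k]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            denom = pos_null.mean() if pos_null.size else np.nan
            p = (1 + np.sum(pos_null >= es)) / (1 + pos_null.size) if pos_null.size else 1.0
        else:
            denom = np.abs(neg_null).mean() if neg_null.size else np.nan
            p = (1 + np.sum(neg_null <= es)) / (1 + neg_null.size) if neg_null.size else 1.0
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        null_nes = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else np.empty(0),
                neg_null / np.abs(neg_null).mean() if neg_null.size else np.empty(0),
            ]
        )
        all_null_nes.append(null_nes)
        rows.append(
            {"set": name, "size": k, "es": es, "nes": nes,
             "direction": -1 if es >= 0 else 1, "p": float(p)}
        )
    df = pd.DataFrame(rows).set_index("set")

    # pooled-null FDR per sign
    pooled = np.concatenate(all_null_nes)
    pos_pool = pooled[pooled >= 0]
    neg_pool = pooled[pooled < 0]
    obs = df["nes"].to_numpy()
    q = np.ones(len(df))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(pos_pool >= nes) if pos_pool.size else 1.0
            obs_frac = np.mean(obs[np.isfinite(obs) & (obs >= 0)] >= nes)
        else:
            null_frac = np.mean(neg_pool <= nes) if neg_pool.size else 1.0
            obs_frac = np.mean(obs[np.isfinite(obs) & (obs < 0)] <= nes)
        q[i] = min(1.0, null_frac / max(obs_frac, 1e-12))
    df["q"] = q
    df["cohort"] = cohort
    df["view"] = view
    return df.reset_index()


def recurrent_pathways(
    results: pd.DataFrame, fdr_cut: float = 0.25, min_hits: int = 5
) -> pd.DataFrame:
    """Sets enriched (q <= fdr_cut) in at least ``min_hits`` of the
    cohort x view analyses, with per-analysis signed enrichment level
    z = Phi^-1(1 - q) carrying the direction sign."""
    res = results.copy()
    res["hit"] = res["q"] <= fdr_cut
    counts = res.groupby("set")["hit"].sum()
    keep = counts[counts >= min_hits].index
    res = res[res["set"].isin(keep)].copy()
    qc = res["q"].clip(Q_CLIP, 1 - Q_CLIP)
    res["enrichment_z"] = res["direction"] * norm.isf(qc)
    out = res.pivot_table(index="set", columns=["cohort", "view"],
                          values="enrichment_z", aggfunc="first")
    out.insert(0, ("n_hits", ""), counts.loc[out.index])
    return out.sort_values(("n_hits", ""), ascending=False)


def cross_cohort_concordance(
    results: pd.DataFrame,
    view: str,
    direction: int,
    fdr_grid: list[float],
    jaccard: bool = False,
) -> pd.DataFrame:
    """Overlap of enriched-set selections between every cohort pair.

    At each FDR threshold and for the given direction and view, the
    concordance of cohorts A and B is |A n B| / min(|A|, |B|) (overlap
    coefficient; ``jaccard=True`` divides by |A u B| instead).  A pair
    where either selection is empty yields NaN, not zero.
    """
    sub = results[(results["view"] == view) & (results["direction"] == direction)]
    cohorts = sorted(sub["cohort"].unique())
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    rows = []
    for thr in fdr_grid:
        sel = {
            c: set(sub[(sub["cohort"] == c) & (sub["q"] <= thr)]["set"])
            for c in cohorts
        }
        for i, a in enumerate(cohorts):
            for b in cohorts[i + 1:]:
                A, B = sel[a], sel[b]
                if not A or not B:
                    val = np.nan
                else:
                    inter = len(A & B)
                    val = inter / (len(A | B) if jaccard else min(len(A), len(B)))
                rows.append(
                    {"fdr": thr, "cohort_a": a, "cohort_b": b, "concordance": val}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-sample (individualized) enrichment


def single_sample_scores(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    min_size: int = 5,
    weight: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene-set x sample matrix of single-sample enrichment values.

    Per sample, genes are ranked by expression (descending rank value N
    for the highest); walking down the ranking, the score is the summed
    difference between the rank-weighted in-set empirical CDF (weights
    rank^weight) and the unweighted out-of-set CDF.  With
    ``normalize=True`` each set's row is scaled by its range across
    samples so Cox coefficients are comparable across sets.
    """
    genes = expr.gene_ids
    values = expr.values
    N = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    kept = {}
    for name, members in sets.items():
        idx = np.array(sorted({gene_idx[g] for g in members if g in gene_idx}), dtype=int)
        if len(idx) >= min_size and len(idx) < N:
            kept[name] = idx
    if not kept:
        raise ValueError("no gene set survives size filtering")

    set_masks = {}
    for name, idx in kept.items():
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        set_masks[name] = mask

    scores = np.zeros((len(kept), expr.shape[1]))
    for s in range(expr.shape[1]):
        col = values[:, s]
        if np.ptp(col) == 0:
            raise ValueError(f"sample {expr.sample_ids[s]!r} is constant and unrankable")
        order = np.argsort(-col, kind="stable")  # gene indices, highest first
        rank_value = np.arange(N, 0, -1, dtype=float)  # N for the top gene
        w = rank_value**weight
        for t, (name, mask) in enumerate(set_masks.items()):
            m = mask[order]
            k = int(m.sum())
            win = np.where(m, w, 0.0)
            p_in = np.cumsum(win) / win.sum()
            p_out = np.cumsum(~m) / (N - k)
            scores[t, s] = float(np.sum(p_in - p_out))
    df = pd.DataFrame(scores, index=list(kept.keys()), columns=expr.sample_ids)
    if normalize:
        rng_ = df.max(axis=1) - df.min(axis=1)
        rng_ = rng_.replace(0.0, 1.0)
        df = df.div(rng_, axis=0)
    return df


def geneset_survival_pvalues(scores: pd.DataFrame, surv: SurvivalTable) -> pd.DataFrame:
    """Univariate Cox of survival on each gene set's score vector."""
    surv = surv.reorder(list(scores.columns))
    ranking = univariate_cox_from_matrix(scores.to_numpy(), list(scores.index), surv)
    return ranking.table.rename_axis("set")


def normal_tumor_log_ratio(
    p_normal: pd.Series, p_tumor: pd.Series, top_n: int = 100
) -> pd.DataFrame:
    """Rank gene sets by how much more predictive they are in one
    compartment: log(p_tumor / p_normal), positive = more predictive in
    normal ("Normal Associated"), negative = "Tumor Associated".

    Returns the top ``top_n`` sets by |log ratio| (ties broken by set
    name); zero p-values are clipped at machine minimum with a warning.
    """
    common = sorted(set(p_normal.index) & set(p_tumor.index))
    if not common:
        raise ValueError("no common gene sets")
    pn = p_normal.loc[common].astype(float)
    pt = p_tumor.loc[common].astype(float)
    tiny = np.finfo(float).tiny
    if (pn <= 0).any() or (pt <= 0).any():
        logger.warning("zero p-values clipped at machine minimum")
    pn = pn.clip(lower=tiny)
    pt = pt.clip(lower=tiny)
    log_ratio = np.log(pt / pn)
    df = pd.DataFrame(
        {
            "log_ratio": log_ratio,
            "label": np.where(log_ratio > 0, "Normal Associated", "Tumor Associated"),
            "p_normal": pn,
            "p_tumor": pt,
        }
    )
    df = df.loc[
        sorted(df.index, key=lambda name: (-abs(df.loc[name, "log_ratio"]), name))
    ]
    return df.head(top_n)
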