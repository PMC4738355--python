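"""Leave-pair-out pairwise risk-order evaluation (consistency matrices).

For every unordered patient pair (i, j) an elastic-net Cox model is fit
on all other patients (features PCA-reduced once beforehand) and asked
which of the two held-out patients is at higher risk.  Aggregating over
random runs gives the probability matrix M (M_ij = probability the
model ranks i riskier than j).  The censoring-aware reference M_r reads
the same ordering off the observed data: a pair is *identifiable* when
the smaller observed time belongs to a death and times are untied, in
which case the earlier death marks the higher-risk patient; all other
entries are 0.5.  The consistency matrix C = 1 - |M - M_r| scores the
agreement (1 = perfect, 0 = maximal disagreement); per-patient means
over identifiable pairs flag patients whose survival is consistently
mispredicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureView, SurvivalTable
from .survival import (
    DEFAULT_MIXING,
    _coxnet_path,
    _event_folds,
    _surv_y,
    cox_deviance,
    pca_reduce,
)

logger = logging.getLogger(__name__)


@dataclass
class PairwiseMatrices:
    """M (predicted pairwise risk-order probabilities), M_r (observed
    reference), C (agreement), over a fixed patient order."""

    patient_ids: list[str]
    M: np.ndarray
    M_r: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        for name in ("M", "M_r", "C"):
            if getattr(self, name).shape != (n, n):
                raise ValueError(f"{name} shape must be ({n}, {n})")


def comparable_pairs(surv: SurvivalTable) -> np.ndarray:
    """Boolean matrix of identifiable pairs under right censoring.

    Pair (i, j) is identifiable iff the smaller observed time is an
    event and the times are not tied; the diagonal is False.
    """
    t = surv.time
    e = surv.event.astype(bool)
    earlier_event = (t[:, None] < t[None, :]) & e[:, None]
    ident = earlier_event | earlier_event.T
    np.fill_diagonal(ident, False)
    return ident


def reference_matrix(surv: SurvivalTable) -> np.ndarray:
    """M_r: 1 where row patient is identifiably higher-risk, 0 where the
    column patient is, 0.5 anywhere the order is uncertain (and on the
    diagonal)."""
    t = surv.time
    e = surv.event.astype(bool)
    row_riskier = (t[:, None] < t[None, :]) & e[:, None]
    M_r = np.full((len(t), len(t)), 0.5)
    M_r[row_riskier] = 1.0
    M_r[row_riskier.T] = 0.0
    return M_r


def probability_matrix(
    view: FeatureView,
    surv: SurvivalTable,
    n_runs: int = 20,
    seed: int = 0,
    mixing: float = DEFAULT_MIXING,
    max_components: int | None = None,
    n_folds: int = 5,
    n_alphas: int = 10,
) -> np.ndarray:
    """Leave-pair-out probability matrix M over ``n_runs`` random runs.

    The view is PCA-reduced once on all patients.  Each run selects the
    penalty strength by ``n_folds``-fold cross-validation on the full
    reduced design (fold randomness is the run's randomness), then for
    every unordered pair (i, j) fits the penalized Cox model at that
    penalty on all patients except i and j and compares the two
    held-out risk predictions; ties count 0.5.  M_ij is the fraction of
    runs ranking i riskier than j.  Because runs that select the same
    penalty produce identical fits, pair predictions are cached per
    distinct penalty value.  A leave-pair-out training set without
    events invalidates that pair for the run (denominator adjusted).
    """
    surv = surv.reorder(view.patient_ids)
    n = view.n_patients
    if n < 4:
        raise ValueError("need at least 4 patients for leave-pair-out")
    design = pca_reduce(view, max_components)
    X = design.scores
    time, event = surv.time, surv.event
    y_all = _surv_y(time, event)

    # penalty grid from the full-data path; per-run CV picks one value
    path = _coxnet_path(X, y_all, mixing, n_alphas=n_alphas)
    alphas = np.asarray(path.alphas_)
    rng = np.random.default_rng(seed)

    chosen: list[float] = []
    for _ in range(n_runs):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        folds = _event_folds(event, n_folds, fold_seed)
        cv_dev = np.zeros(len(alphas))
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            sub = _coxnet_path(X[train], y_all[train], mixing, alphas=list(alphas))
            lp_all = X @ sub.coef_
            lp_train = X[train] @ sub.coef_
            for a in range(len(alphas)):
                cv_dev[a] += cox_deviance(lp_all[:, a], time, event) - cox_deviance(
                    lp_train[:, a], time[train], event[train]
                )
        chosen.append(float(alphas[int(np.argmin(cv_dev))]))

    iu, ju = np.triu_indices(n, k=1)
    wins = np.zeros((n, n))
    valid = np.zeros((n, n))
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for lam in chosen:
        if lam not in cache:
            cache[lam] = _leave_pair_out(X, time, event, lam, mixing)
        w, v = cache[lam]
        wins += w
        valid += v
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(valid > 0, wins / np.maximum(valid, 1), 0.5)
    np.fill_diagonal(M, 0.5)
    if (valid[iu, ju] == 0).any():
        logger.warning("%d pairs had no valid runs; entries left at 0.5",
                       int((valid[iu, ju] == 0).sum()))
    return M


def _leave_pair_out(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, lam: float, mixing: float
) -> tuple[np.ndarray, np.ndarray]:
    """One deterministic leave-pair-out sweep at a fixed penalty.

    Returns (wins, valid): wins_ij in {0, 0.5, 1} where defined and the
    validity indicator (pairs whose training set lacked events are
    invalid).
    """
    n = X.shape[0]
    wins = np.zeros((n, n))
    valid = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            train = idx[(idx != i) & (idx != j)]
            if event[train].sum() < 1:
                continue
            model = _coxnet_path(
                X[train], _surv_y(time[train], event[train]), mixing, alphas=[lam]
            )
            coef = model.coef_[:, 0]
            r_i, r_j = float(X[i] @ coef), float(X[j] @ coef)
            if r_i > r_j:
                w = 1.0
            elif r_i < r_j:
                w = 0.0
            else:
                w = 0.5
            wins[i, j] += w
            wins[j, i] += 1.0 - w
            valid[i, j] += 1
            valid[j, i] += 1
    return wins, valid


def probability_matrix_from_scores(risk: np.ndarray) -> np.ndarray:
    """Deterministic M from fixed per-patient risk scores (e.g. a known
    linear predictor): M_ij = 1 if risk_i > risk_j, 0.5 on ties."""
    risk = np.asarray(risk, dtype=float)
    M = np.where(
        risk[:, None] > risk[None, :], 1.0,
        np.where(risk[:, None] < risk[None, :], 0.0, 0.5),
    )
    np.fill_diagonal(M, 0.5)
    return M


def consistency(M: np.ndarray, M_r: np.ndarray, absolute_difference: bool = False) -> np.ndarray:
    """Agreement matrix C = 1 - |M - M_r| (1 = perfect agreement).

    ``absolute_difference=True`` returns the raw difference |M - M_r|
    instead (0 = perfect agreement).
    """
    M = np.asarray(M, float)
    M_r = np.asarray(M_r, float)
    if M.shape != M_r.shape:
        raise ValueError("M and M_r shapes must match")
    diff = np.abs(M - M_r)
    return diff if absolute_difference else 1.0 - diff


def mean_consistency(C: np.ndarray, identifiable: np.ndarray) -> float:
    """Mean of C over identifiable (off-diagonal) pairs."""
    mask = np.asarray(identifiable, bool)
    if not mask.any():
        raise ValueError("no identifiable pairs")
    return float(C[mask].mean())


def per_patient_consistency(
    C: np.ndarray,
    identifiable: np.ndarray,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-patient mean consistency over identifiable pairs with outlier flags.

    Outliers fall below Q1 - 1.5 IQR of the per-patient means; patients
    with no identifiable pair get a missing mean and no flag.
    """
    C = np.asarray(C, float)
    mask = np.asarray(identifiable, bool)
    n = C.shape[0]
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]
    means = np.full(n, np.nan)
    counts = mask.sum(axis=1)
    for i in range(n):
        if counts[i] > 0:
            means[i] = C[i, mask[i]].mean()
    ok = ~np.isnan(means)
    if ok.any():
        q1, q3 = np.percentile(means[ok], [25, 75])
        lo = q1 - 1.5 * (q3 - q1)
        outlier = ok & (means < lo)
    else:
        outlier = np.zeros(n, dtype=bool)
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "mean_consistency": means,
            "n_identifiable_pairs": counts,
            "outlier": outlier,
        }
    )


def pairwise_matrices(
    view: FeatureView,
    surv: SurvivalTable,
    n_runs: int = 20,
    seed: int = 0,
    **kwargs,
) -> PairwiseMatrices:
    """Convenience wrapper: M, M_r and C for one view in patient order."""
    surv_o = surv.reorder(view.patient_ids)
    M = probability_matrix(view, surv_o, n_runs=n_runs, seed=seed, **kwargs)
    M_r = reference_matrix(surv_o)
    return PairwiseMatrices(list(view.patient_ids), M, M_r, consistency(M, M_r))
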