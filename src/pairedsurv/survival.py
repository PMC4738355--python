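"""Survival prediction per feature view: PCA + elastic-net Cox, and forests.

High-dimensional views are first reduced to principal-component scores
(at most n_samples - 1 components), then an elastic-net penalized Cox
model is fit on the scores, with the penalty strength chosen by
stratified K-fold cross-validation on the partial-likelihood deviance.
Views are compared by the *mean cross-validation error*: for fold k,
the difference between the model deviance evaluated on the full cohort
and on the cohort minus fold k, where the model is fit without fold k —
the deviance attributable to the held-out fold.  A random survival
forest with out-of-bag concordance error provides a nonparametric
companion comparison.

Deviance is -2 x the Breslow log partial likelihood evaluated with the
fitted linear predictor on the stated subset (the saturated-model
reference is not defined for Cox regression, so no constant is
subtracted; only deviance differences are ever interpreted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import FeatureView, PairedCohort, SurvivalTable, make_feature_view

logger = logging.getLogger(__name__)

DEFAULT_MIXING = 0.01  # elastic-net l1_ratio: nearly ridge
DEFAULT_FOLDS = 5
DEFAULT_RUNS = 20
DEFAULT_TREES = 10_000


def cox_deviance(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """-2 x Breslow log partial likelihood of a linear predictor.

    Ties are handled with the Breslow approximation: every subject with
    time >= t_i is in the risk set of an event at t_i, and tied events
    share that risk set.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_s, e_s, lp_s = time[order], event[order], lp[order]
    # log of suffix sums of exp(lp) over subjects with time >= t, stably
    m = lp_s.max()
    rev_cumsum = np.cumsum(np.exp(lp_s - m)[::-1])[::-1]
    log_risk = m + np.log(rev_cumsum)
    # risk set of an event at t_i starts at the first index with time == t_i
    first_idx = np.searchsorted(t_s, t_s, side="left")
    ll = float(np.sum((lp_s - log_risk[first_idx])[e_s == 1]))
    return -2.0 * ll


@dataclass
class ReducedDesign:
    """PCA scores of a feature view plus the projection for new samples."""

    patient_ids: list[str]
    scores: np.ndarray  # patients x components
    loadings: np.ndarray  # components x features
    mean: np.ndarray  # feature means on the fitting samples
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_reduce(view: FeatureView, max_components: int | None = None) -> ReducedDesign:
    """Column-centered SVD scores; zero-variance directions dropped."""
    X = view.X
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    k = min(rank, X.shape[0] - 1)
    if max_components is not None:
        k = min(k, max_components)
    scores = U[:, :k] * s[:k]
    return ReducedDesign(
        patient_ids=list(view.patient_ids),
        scores=scores,
        loadings=Vt[:k],
        mean=mean,
        explained_variance=s[:k] ** 2 / (X.shape[0] - 1),
    )


@dataclass
class CoxFit:
    """Elastic-net Cox fit on component scores."""

    coefficients: np.ndarray
    mixing: float
    penalty_strength: float
    alphas: np.ndarray
    cv_deviance: np.ndarray  # summed held-out deviance difference per alpha
    seed: int

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.coefficients


def _surv_y(time: np.ndarray, event: np.ndarray):
    return Surv.from_arrays(event=event.astype(bool), time=time)


def _event_folds(event: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Fold test-index arrays, stratified by event status."""
    if event.sum() < n_folds:
        raise ValueError(
            f"need at least {n_folds} events for {n_folds}-fold CV, have {int(event.sum())}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(event)), event)]


def _coxnet_path(X, y, mixing, alphas=None, n_alphas=20):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = CoxnetSurvivalAnalysis(
            l1_ratio=mixing,
            alphas=alphas,
            n_alphas=n_alphas,
            alpha_min_ratio=0.01,
            fit_baseline_model=False,
        )
        model.fit(X, y)
    return model


def fit_elastic_net_cox(
    design: ReducedDesign | np.ndarray,
    surv: SurvivalTable,
    mixing: float = DEFAULT_MIXING,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    n_alphas: int = 20,
) -> CoxFit:
    """Cox partial-likelihood maximization with the elastic-net penalty
    lambda * [ mixing * sum|b_j| + (1 - mixing)/2 * sum b_j^2 ].

    The penalty strength is grid-searched on a path of ``n_alphas``
    values; each candidate is scored by the summed held-out deviance
    difference over ``n_folds`` event-stratified folds (fit without the
    fold, deviance on all data minus deviance on the training part),
    and the minimizer is refit on all data.
    """
    X = design.scores if isinstance(design, ReducedDesign) else np.asarray(design, float)
    if surv.n_events < 1:
        raise ValueError("at least one event is required")
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.info("dropping %d constant design columns", int((~keep).sum()))
    Xk = X[:, keep]
    y = _surv_y(surv.time, surv.event)
    path = _coxnet_path(Xk, y, mixing, n_alphas=n_alphas)
    alphas = np.asarray(path.alphas_)

    folds = _event_folds(surv.event, n_folds, seed)
    cv_dev = np.zeros(len(alphas))
    for test in folds:
        train = np.setdiff1d(np.arange(len(surv.time)), test)
        sub = _coxnet_path(Xk[train], y[train], mixing, alphas=list(alphas))
        coefs = sub.coef_  # features x alphas
        lp_all = Xk @ coefs
        lp_train = Xk[train] @ coefs
        for a in range(len(alphas)):
            d_all = cox_deviance(lp_all[:, a], surv.time, surv.event)
            d_train = cox_deviance(lp_train[:, a], surv.time[train], surv.event[train])
            cv_dev[a] += d_all - d_train
    best = int(np.argmin(cv_dev))
    coef_full = np.zeros(X.shape[1])
    coef_full[keep] = path.coef_[:, best]
    return CoxFit(
        coefficients=coef_full,
        mixing=mixing,
        penalty_strength=float(alphas[best]),
        alphas=alphas,
        cv_deviance=cv_dev,
        seed=seed,
    )


def mean_cv_error(
    view: FeatureView,
    surv: SurvivalTable,
    mixing: float = DEFAULT_MIXING,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    max_components: int | None = None,
    pca_per_fold: bool = True,
    n_alphas: int = 20,
    max_refolds: int = 5,
) -> float:
    """Mean over folds of D(full) - D(minus fold k) under the fold-k model.

    The pipeline (PCA reduction, then elastic-net Cox with internal
    penalty selection) is refit on each fold's training part; held-out
    rows are projected with the training loadings so no information
    leaks.  ``pca_per_fold=False`` instead reduces once on all data
    before cross-validation.  A fold assignment that leaves a training
    set without events is redrawn with a new seed (warning logged).
    """
    surv = surv.reorder(view.patient_ids)
    time, event = surv.time, surv.event
    n = len(time)
    global_design = None if pca_per_fold else pca_reduce(view, max_components)

    for attempt in range(max_refolds):
        folds = _event_folds(event, n_folds, seed + attempt)
        if all(event[np.setdiff1d(np.arange(n), t)].sum() >= 1 for t in folds):
            if attempt:
                logger.warning("refolded %d time(s) to keep events in every training set",
                               attempt)
            break
    else:
        raise ValueError("could not build folds with events in every training set")

    errors = []
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        sub_surv = SurvivalTable(
            [surv.patient_ids[i] for i in train], time[train], event[train]
        )
        if pca_per_fold:
            train_view = FeatureView(
                label=view.label,
                patient_ids=[view.patient_ids[i] for i in train],
                feature_names=view.feature_names,
                X=view.X[train],
            )
            design = pca_reduce(train_view, max_components)
            scores_train = design.scores
            scores_all = design.transform(view.X)
        else:
            design = global_design
            scores_train = design.scores[train]
            scores_all = design.scores
        fit = fit_elastic_net_cox(
            scores_train, sub_surv, mixing=mixing, n_folds=n_folds,
            seed=(seed * 1009 + k) % (2**31 - 1), n_alphas=n_alphas,
        )
        d_all = cox_deviance(fit.predict(scores_all), time, event)
        d_train = cox_deviance(fit.predict(scores_train), time[train], event[train])
        errors.append(d_all - d_train)
    return float(np.mean(errors))


def fit_random_survival_forest(
    view: FeatureView,
    surv: SurvivalTable,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> tuple[RandomSurvivalForest, float]:
    """Log-rank-split survival forest; returns (model, out-of-bag error).

    The OOB error is 1 minus Harrell's concordance index of the
    out-of-bag ensemble risk predictions against observed survival.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    surv = surv.reorder(view.patient_ids)
    if surv.n_events < 2:
        raise ValueError("need at least 2 events for a survival forest")
    y = _surv_y(surv.time, surv.event)
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        oob_score=True,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(view.X, y)
    return forest, float(1.0 - forest.oob_score_)


@dataclass
class ViewComparison:
    """Per-view mean-CV-error distributions (and optional forest OOB errors)."""

    cv_errors: dict[str, list[float]]
    oob_errors: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, errs in self.cv_errors.items():
            rows.append(
                {
                    "view": label,
                    "median_cv_error": float(np.median(errs)),
                    "mean_cv_error": float(np.mean(errs)),
                    "n_runs": len(errs),
                    "oob_error": self.oob_errors.get(label, np.nan),
                }
            )
        return (
            pd.DataFrame(rows)
            .sort_values("median_cv_error")
            .reset_index(drop=True)
        )

    def best_view(self) -> str:
        return str(self.summary().iloc[0]["view"])


def compare_views(
    cohort: PairedCohort,
    surv: SurvivalTable,
    views: list[str],
    n_runs: int = DEFAULT_RUNS,
    seed: int = 0,
    mixing: float = DEFAULT_MIXING,
    n_folds: int = DEFAULT_FOLDS,
    max_components: int | None = None,
    include_forest: bool = False,
    n_trees: int = DEFAULT_TREES,
) -> ViewComparison:
    """Mean-CV-error distributions across runs for each requested view.

    Each run re-randomizes the outer folds through a seed derived from
    ``seed``; the same run seeds are used for every view so run-level
    differences are paired across views.
    """
    if not views:
        raise ValueError("need at least one view label")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    cv_errors: dict[str, list[float]] = {}
    oob: dict[str, float] = {}
    for label in views:
        view = make_feature_view(cohort, label)
        cv_errors[label] = [
            mean_cv_error(
                view, surv, mixing=mixing, n_folds=n_folds,
                seed=int(s), max_components=max_components,
            )
            for s in run_seeds
        ]
        if include_forest:
            _, err = fit_random_survival_forest(view, surv, n_trees=n_trees, seed=seed)
            oob[label] = err
    return ViewComparison(cv_errors=cv_errors, oob_errors=oob)
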