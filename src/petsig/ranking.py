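"""Consensus machine-learning gene ranking.

The ranking engine reproduces a resampling-consensus feature-selection
procedure: the binary prediction target is derived from PFS follow-up (for
the hybrid-Lasso arm a one-dimensional fuzzy C-means clustering of the
follow-up times chooses the time threshold that defines an "early
progressor"), the cohort is split 100 times into stratified 67/33
train/test sets, a Random Forest and an L1-penalised logistic regression
rank all genes on every training set, per-method ranks are averaged across
splits, and the consensus is the intersection of the two top-k lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .containers import CohortTable
from .simulate import child_seed

__all__ = [
    "FCMResult",
    "EventLabeling",
    "SplitPlan",
    "FeatureRanking",
    "AggregatedRanking",
    "ConsensusSet",
    "fcm_cluster",
    "fcm_objective",
    "define_event_label",
    "make_splits",
    "rank_random_forest",
    "rank_hybrid_lasso",
    "aggregate_rankings",
    "consensus_top_k",
]


# ---------------------------------------------------------------------------
# Fuzzy C-means on one-dimensional outcomes
# ---------------------------------------------------------------------------

@dataclass
class FCMResult:
    centroids: np.ndarray  # sorted ascending
    memberships: np.ndarray  # n x c, rows sum to 1
    fuzzifier_m: float
    threshold: float  # outcome value where the two memberships cross
    iterations: int
    objective_trace: np.ndarray  # value of sum_ij u_ij^m d_ij^2 per iteration


def fcm_objective(values: np.ndarray, centroids: np.ndarray, memberships: np.ndarray, m: float) -> float:
    """The fuzzy C-means cost sum_ij u_ij^m * (x_i - c_j)^2."""
    d2 = (np.asarray(values, float)[:, None] - np.asarray(centroids, float)[None, :]) ** 2
    return float(np.sum(memberships**m * d2))


def _fcm_memberships(values: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d = np.abs(values[:, None] - centroids[None, :])
    u = np.empty_like(d)
    zero = d < 1e-300
    any_zero = zero.any(axis=1)
    # crisp assignment where a point coincides with a centroid
    u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    ok = ~any_zero
    if ok.any():
        with np.errstate(over="ignore", divide="ignore"):
            ratio = d[ok][:, :, None] / d[ok][:, None, :]
            u[ok] = 1.0 / np.sum(ratio ** (2.0 / (m - 1.0)), axis=2)
        u[ok] /= u[ok].sum(axis=1, keepdims=True)  # exact row normalization
    return u


def fcm_cluster(
    values,
    c: int = 2,
    fuzzifier_m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> FCMResult:
    """Classic fuzzy C-means on a one-dimensional outcome vector.

    Alternates the membership update u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1))
    with the u^m-weighted centroid update until the centroid shift falls
    below ``tol``.  For two clusters the event-definition threshold is the
    point of equal membership, i.e. the centroid midpoint.
    """
    x = np.asarray(values, float).ravel()
    if fuzzifier_m <= 1:
        raise ValueError("fuzzifier_m must exceed 1")
    if c < 2:
        raise ValueError("need at least two clusters")
    if len(np.unique(x)) < c:
        raise ValueError("values are degenerate: fewer distinct values than clusters")

    # spread initial centroids over the inner quantiles
    qs = np.linspace(0.25, 0.75, c)
    centroids = np.quantile(x, qs)
    if len(np.unique(centroids)) < c:  # heavily tied data; fall back to range
        centroids = np.linspace(x.min(), x.max(), c + 2)[1:-1]

    trace = []
    for it in range(1, max_iter + 1):
        u = _fcm_memberships(x, centroids, fuzzifier_m)
        trace.append(fcm_objective(x, centroids, u, fuzzifier_m))
        um = u**fuzzifier_m
        new_centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break
    else:
        raise RuntimeError(f"fuzzy C-means did not converge in {max_iter} iterations")

    u = _fcm_memberships(x, centroids, fuzzifier_m)
    trace.append(fcm_objective(x, centroids, u, fuzzifier_m))
    order = np.argsort(centroids)
    centroids = centroids[order]
    u = u[:, order]
    if abs(centroids[-1] - centroids[0]) < 1e-12:
        raise RuntimeError("fuzzy C-means collapsed to coincident centroids")
    threshold = float(0.5 * (centroids[0] + centroids[1]))
    return FCMResult(
        centroids=centroids,
        memberships=u,
        fuzzifier_m=fuzzifier_m,
        threshold=threshold,
        iterations=it,
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Event definition
# ---------------------------------------------------------------------------

@dataclass
class EventLabeling:
    labels: np.ndarray  # 0/1 per patient
    threshold_months: float | None
    source: str  # "fcm" or "recorded"


def define_event_label(cohort: CohortTable, mode: str = "fcm") -> EventLabeling:
    """Binary prediction target for the ML rankers.

    ``recorded`` uses the progression indicator as-is.  ``fcm`` clusters the
    follow-up times into an early and a late group and labels a patient 1
    only when progression was recorded at or before the crossing threshold
    (early progressor); patients censored early stay 0.
    """
    if cohort.n_patients < 2:
        raise ValueError("cohort too small to define an event label")
    if mode == "recorded":
        return EventLabeling(labels=cohort.events.copy(), threshold_months=None, source="recorded")
    if mode != "fcm":
        raise ValueError(f"unknown labeling mode {mode!r}")
    res = fcm_cluster(cohort.times)
    labels = ((cohort.events == 1) & (cohort.times <= res.threshold)).astype(int)
    return EventLabeling(labels=labels, threshold_months=res.threshold, source="fcm")


# ---------------------------------------------------------------------------
# Event-rate-preserving random splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    n_splits: int
    train_fraction: float
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_splits(
    cohort: CohortTable,
    n_splits: int = 100,
    train_fraction: float = 0.67,
    seed: int = 0,
) -> SplitPlan:
    """Random train/test splits stratified on the recorded event indicator.

    Events and non-events are sampled separately at ``train_fraction`` with
    half-up rounding, so every split preserves the cohort event rate up to
    integer rounding.
    """
    events = cohort.events
    idx_ev = np.flatnonzero(events == 1)
    idx_no = np.flatnonzero(events == 0)
    if len(idx_ev) < 2 or len(idx_no) < 2:
        raise ValueError("both outcome classes need at least two members to stratify")
    n_tr_ev = _round_half_up(train_fraction * len(idx_ev))
    n_tr_no = _round_half_up(train_fraction * len(idx_no))
    if n_tr_ev == 0 or n_tr_no == 0:
        raise ValueError("train_fraction too small: a class has an empty training part")
    if n_tr_ev == len(idx_ev) or n_tr_no == len(idx_no):
        raise ValueError("train_fraction too large: a class has an empty test part")

    splits = []
    for s in range(n_splits):
        rng = np.random.default_rng(child_seed(seed, 1, s))
        tr_ev = rng.permutation(idx_ev)[:n_tr_ev]
        tr_no = rng.permutation(idx_no)[:n_tr_no]
        train = np.sort(np.concatenate([tr_ev, tr_no]))
        mask = np.ones(cohort.n_patients, bool)
        mask[train] = False
        test = np.flatnonzero(mask)
        splits.append((train, test))
    return SplitPlan(n_splits=n_splits, train_fraction=train_fraction, splits=splits, seed=seed)


# ---------------------------------------------------------------------------
# Per-split feature rankings
# ---------------------------------------------------------------------------

@dataclass
class FeatureRanking:
    method: str
    split_id: int
    genes: tuple[str, ...]
    weights: np.ndarray  # importance score per gene, >= 0
    ranks: np.ndarray  # permutation of 1..n_genes, 1 = most important


def _weights_to_ranks(genes: tuple[str, ...], weights: np.ndarray) -> np.ndarray:
    """Rank descending by weight; ties (including the all-zero block) broken
    alphabetically by gene symbol."""
    order = sorted(range(len(genes)), key=lambda i: (-weights[i], genes[i]))
    ranks = np.empty(len(genes), int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; cannot rank features")
    return labels


def rank_random_forest(
    train_expr: pd.DataFrame,
    train_labels,
    n_trees: int = 500,
    seed: int = 0,
    split_id: int = 0,
) -> FeatureRanking:
    """Classification-forest ranking; weight = mean impurity decrease."""
    labels = _check_labels(np.asarray(train_labels))
    genes = tuple(train_expr.columns)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train_expr.to_numpy(float), labels)
    weights = forest.feature_importances_.copy()
    return FeatureRanking(
        method="random_forest",
        split_id=split_id,
        genes=genes,
        weights=weights,
        ranks=_weights_to_ranks(genes, weights),
    )


def rank_hybrid_lasso(
    train_expr: pd.DataFrame,
    train_labels,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    split_id: int = 0,
) -> FeatureRanking:
    """L1-penalised logistic ranking on the (FCM-derived) binary label.

    The penalty is chosen on a lambda grid by cross-validated deviance
    minimum; the weight of a gene is |coefficient| at the chosen penalty.
    Genes shrunk exactly to zero share the worst rank block, ordered
    alphabetically.
    """
    labels = _check_labels(np.asarray(train_labels))
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 0, 10)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    genes = tuple(train_expr.columns)
    X = train_expr.to_numpy(float)

    def _l1_fit(Xf, yf, lam):
        # sklearn's C multiplies the summed loss, so C = 1/(lam * n) gives a
        # per-observation penalty weight of lam (glmnet convention)
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam * len(yf)), solver="liblinear",
            max_iter=2000, random_state=seed,
        ).fit(Xf, yf)

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    deviance = np.zeros(len(lambda_grid))
    for tr, va in cv.split(X, labels):
        for j, lam in enumerate(lambda_grid):
            prob = _l1_fit(X[tr], labels[tr], lam).predict_proba(X[va])[:, 1]
            deviance[j] += log_loss(labels[va], prob, labels=[0, 1]) * len(va)
    # deviance minimum; ties resolved toward the stronger penalty
    best = np.flatnonzero(deviance <= deviance.min() + 1e-12)[-1]
    weights = np.abs(_l1_fit(X, labels, lambda_grid[best]).coef_.ravel())
    return FeatureRanking(
        method="hybrid_lasso",
        split_id=split_id,
        genes=genes,
        weights=weights,
        ranks=_weights_to_ranks(genes, weights),
    )


# ---------------------------------------------------------------------------
# Aggregation and consensus
# ---------------------------------------------------------------------------

@dataclass
class AggregatedRanking:
    method: str
    mean_rank: pd.Series  # indexed by gene
    order: tuple[str, ...]  # ascending mean rank, ties alphabetical

    def top_k(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


@dataclass
class ConsensusSet:
    k: int
    genes: tuple[str, ...]  # alphabetical


def aggregate_rankings(rankings: list[FeatureRanking]) -> AggregatedRanking:
    """Average per-gene ranks across splits and order ascending."""
    if not rankings:
        raise ValueError("no rankings to aggregate")
    genes = rankings[0].genes
    methods = {r.method for r in rankings}
    if len(methods) != 1:
        raise ValueError(f"mixed methods in aggregation: {sorted(methods)}")
    for r in rankings:
        if r.genes != genes:
            raise ValueError("rankings cover different gene sets")
    mat = np.vstack([r.ranks for r in rankings])
    mean_rank = pd.Series(mat.mean(axis=0), index=list(genes))
    order = tuple(sorted(genes, key=lambda g: (mean_rank[g], g)))
    return AggregatedRanking(method=rankings[0].method, mean_rank=mean_rank, order=order)


def consensus_top_k(agg_a: AggregatedRanking, agg_b: AggregatedRanking, k: int = 10) -> ConsensusSet:
    """Genes present in both methods' top-k lists, alphabetically ordered."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(agg_a.order) or k > len(agg_b.order):
        raise ValueError("k exceeds the number of ranked genes")
    common = sorted(set(agg_a.top_k(k)) & set(agg_b.top_k(k)))
    return ConsensusSet(k=k, genes=tuple(common))


# ---------------------------------------------------------------------------
# Convenience driver used by the pipeline and the acceptance checks
# ---------------------------------------------------------------------------

def consensus_ranking(
    cohort: CohortTable,
    n_splits: int = 100,
    k: int = 10,
    n_trees: int = 500,
    cv_folds: int = 5,
    rf_label_mode: str = "recorded",
    seed: int = 0,
) -> dict:
    """Run the full consensus-ranking stage on one cohort.

    Returns the per-method aggregated rankings and the consensus set.  The
    Random Forest arm trains on ``rf_label_mode`` labels; the hybrid-Lasso
    arm always trains on the FCM early-progressor label.
    """
    label_rf = define_event_label(cohort, mode=rf_label_mode)
    label_fcm = define_event_label(cohort, mode="fcm")
    plan = make_splits(cohort, n_splits=n_splits, seed=child_seed(seed, 2))
    expr = cohort.expression

    rf_rankings, lasso_rankings = [], []
    for s, (train, _test) in enumerate(plan.splits):
        sub = expr.iloc[train]
        rf_rankings.append(
            rank_random_forest(
                sub, label_rf.labels[train], n_trees=n_trees,
                seed=child_seed(seed, 3, s), split_id=s,
            )
        )
        lasso_rankings.append(
            rank_hybrid_lasso(
                sub, label_fcm.labels[train], cv_folds=cv_folds,
                seed=child_seed(seed, 4, s), split_id=s,
            )
        )
    agg_rf = aggregate_rankings(rf_rankings)
    agg_lasso = aggregate_rankings(lasso_rankings)
    consensus = consensus_top_k(agg_rf, agg_lasso, k=k)
    return {
        "labels_rf": label_rf,
        "labels_fcm": label_fcm,
        "split_plan": plan,
        "agg_rf": agg_rf,
        "agg_lasso": agg_lasso,
        "consensus": consensus,
    }
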