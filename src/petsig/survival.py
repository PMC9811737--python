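"""Cox modelling, genetic score and survival stratification.

The centrepiece is a bootstrap-stabilised multivariable Cox proportional
hazards model: the partial likelihood is maximised by Newton-Raphson
(Breslow tie handling by default, Efron optional), the per-feature
coefficient and its standard error are stabilised as the mean and SD of 500
bootstrap refits, and discrimination is summarised by Harrell's c-index with
a bootstrap optimism correction.  Features significant at alpha enter a
linear genetic score that is dichotomised at the cohort median to define
low- and high-risk groups compared by Kaplan-Meier / log-rank and by
t / chi-square tests on clinical characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from scipy import stats

from .containers import CohortTable, SchemaError

__all__ = [
    "CoxModel",
    "GeneticScore",
    "KMCurve",
    "LogRankResult",
    "GroupComparison",
    "cox_partial_loglik",
    "fit_cox",
    "bootstrap_cox",
    "derive_hr",
    "build_genetic_score",
    "apply_score",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "optimism_corrected_cindex",
    "compare_risk_groups",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to reach the score tolerance."""


# ---------------------------------------------------------------------------
# Partial likelihood and Newton-Raphson fit
# ---------------------------------------------------------------------------

def _sorted_arrays(times, events, X):
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(t):
        X = X.T
    order = np.argsort(t, kind="stable")
    return t[order], e[order], X[order]


def cox_partial_loglik(beta, times, events, X, ties: str = "breslow") -> float:
    """Log partial likelihood at ``beta`` (Breslow or Efron tie handling)."""
    ll, _, _ = _cox_ll_grad_info(np.atleast_1d(np.asarray(beta, float)), *_sorted_arrays(times, events, X), ties)
    return ll


def _cox_ll_grad_info(beta, t, e, X, ties):
    """Log partial likelihood, score vector and observed information.

    Arrays must be sorted ascending in time.  Risk-set sums are suffix sums;
    tied event times are grouped so that all deaths at a time share the same
    risk set (Breslow) or receive Efron's fractional down-weighting.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # rescale for overflow safety; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums: S*(i) = sum over j >= i
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d > 0:
            S0, S1, S2 = s0[i], s1[i], s2[i]
            xsum = X[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            if ties == "breslow":
                ll -= d * np.log(S0)
                grad += xsum - d * S1 / S0
                info += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            elif ties == "efron":
                D0 = w[d_idx].sum()
                D1 = wx[d_idx].sum(axis=0)
                D2 = wxx[d_idx].sum(axis=0)
                for r in range(d):
                    f = r / d
                    S0r = S0 - f * D0
                    S1r = S1 - f * D1
                    S2r = S2 - f * D2
                    ll -= np.log(S0r)
                    grad += xsum / d - S1r / S0r
                    info += S2r / S0r - np.outer(S1r, S1r) / S0r**2
            else:
                raise ValueError(f"unknown ties rule {ties!r}")
        i = j
    return float(ll), grad, info


@dataclass
class CoxModel:
    """A fitted (or bootstrap-stabilised) Cox proportional hazards model."""

    features: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray = field(init=False)
    ci95: np.ndarray = field(init=False)  # (p, 2)
    p: np.ndarray = field(init=False)
    cindex_apparent: float | None = None
    cindex_corrected: float | None = None
    n_boot: int = 0
    ties: str = "breslow"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        hr, ci, p = derive_hr(self.beta, self.se)
        self.hr, self.ci95, self.p = hr, ci, p

    def risk_score(self, cohort: CohortTable) -> np.ndarray:
        return cohort.columns_matrix(self.features) @ self.beta

    def as_dict(self) -> dict:
        return {
            "features": list(self.features),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "hr": self.hr.tolist(),
            "ci95": self.ci95.tolist(),
            "p": self.p.tolist(),
            "cindex_apparent": self.cindex_apparent,
            "cindex_corrected": self.cindex_corrected,
            "n_boot": self.n_boot,
            "ties": self.ties,
        }


def derive_hr(beta, se):
    """Hazard ratio, 95 % CI and two-sided Wald p from (beta, se).

    hr = exp(beta); ci = exp(beta -/+ 1.96*se); p from the standard normal
    tail of beta/se.  se == 0 with beta != 0 yields p = 0 (flagged by the
    caller if needed); beta == 0 gives p = 1.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    se = np.atleast_1d(np.asarray(se, float))
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    hr = np.exp(beta)
    ci = np.stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = np.where(beta == 0, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return hr, ci, p


def fit_cox(
    cohort: CohortTable,
    features: list[str] | tuple[str, ...],
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxModel:
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Standard errors come from the inverse observed information at the
    optimum.  Convergence requires max |score| < tol.  Constant or collinear
    features raise (singular information).
    """
    features = tuple(features)
    X = cohort.columns_matrix(features)
    t, e, Xs = _sorted_arrays(cohort.times, cohort.events, X)
    if e.sum() == 0:
        raise ValueError("no events in cohort; Cox model is undefined")
    if np.any(np.ptp(Xs, axis=0) == 0):
        const = [features[i] for i in range(len(features)) if np.ptp(Xs[:, i]) == 0]
        raise np.linalg.LinAlgError(f"constant covariate(s) {const}: singular information")

    center = Xs.mean(axis=0)
    Xc = Xs - center  # centering leaves beta unchanged, improves conditioning
    beta = np.zeros(len(features))
    ll, grad, info = _cox_ll_grad_info(beta, t, e, Xc, ties)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular information (collinear features?): {exc}")
        # step-halving keeps the likelihood non-decreasing
        for _half in range(40):
            cand = beta + step
            ll_new, grad_new, info_new = _cox_ll_grad_info(cand, t, e, Xc, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    else:
        raise ConvergenceError(f"Cox Newton-Raphson did not reach |score| < {tol}")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular information at optimum: {exc}")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxModel(features=features, beta=beta, se=se, ties=ties)


def bootstrap_cox(
    cohort: CohortTable,
    features: list[str] | tuple[str, ...],
    B: int = 500,
    seed: int = 0,
    ties: str = "breslow",
    max_fail_fraction: float = 0.2,
) -> CoxModel:
    """Bootstrap-stabilised Cox coefficients.

    Patients are resampled with replacement B times; the reported beta is
    the mean of the bootstrap betas and the reported SE their SD.  Hazard
    ratios, CIs and Wald p-values are derived from these.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    features = tuple(features)
    fit_cox(cohort, features, ties=ties)  # must succeed on the full data
    rng = np.random.default_rng(seed)
    n = cohort.n_patients
    betas = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sub = CohortTable(
            data=cohort.data.iloc[idx].assign(patient_id=[f"B{i:05d}" for i in range(n)]),
            gene_cols=cohort.gene_cols,
            clinical_cols=cohort.clinical_cols,
        )
        try:
            betas.append(fit_cox(sub, features, ties=ties).beta)
        except (np.linalg.LinAlgError, ConvergenceError, ValueError):
            failures += 1
    if failures > max_fail_fraction * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed to converge")
    mat = np.vstack(betas)
    beta = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) if len(mat) > 1 else np.zeros(len(features))
    return CoxModel(features=features, beta=beta, se=se, n_boot=B, ties=ties)


# ---------------------------------------------------------------------------
# Genetic score
# ---------------------------------------------------------------------------

@dataclass
class GeneticScore:
    """Named linear combination of gene z-scores with a median cutoff."""

    coefficients: dict[str, float]
    threshold: float | None = None  # cohort median of scores, set on application

    @property
    def formula_text(self) -> str:
        parts = []
        for i, (gene, w) in enumerate(self.coefficients.items()):
            mag = f"{abs(w):.4g}*{gene}"
            if i == 0:
                parts.append(mag if w >= 0 else f"- {mag}")
            else:
                parts.append(("+ " if w >= 0 else "- ") + mag)
        return " ".join(parts)


def build_genetic_score(
    model: CoxModel,
    alpha: float = 0.05,
    force_include: list[str] | tuple[str, ...] | None = None,
) -> GeneticScore:
    """Retain features with Wald p < alpha; ``force_include`` features keep
    their coefficient regardless of significance."""
    force = tuple(force_include or ())
    unknown = [f for f in force if f not in model.features]
    if unknown:
        raise ValueError(f"force_include features not in model: {unknown}")
    coeffs: dict[str, float] = {}
    for i, f in enumerate(model.features):
        if model.p[i] < alpha or f in force:
            coeffs[f] = float(model.beta[i])
    if not coeffs:
        raise ValueError(f"no feature significant at alpha={alpha} and none forced")
    return GeneticScore(coefficients=coeffs)


def apply_score(score: GeneticScore, cohort: CohortTable, threshold: float | None = None):
    """Per-patient score and risk group.

    The dichotomisation threshold defaults to the cohort median of the
    scores; a patient scoring exactly at the median falls in the high-risk
    group (score >= cutoff).  Returns (scores, groups) as pandas Series and
    records the threshold on the score object.
    """
    missing = [g for g in score.coefficients if g not in cohort.data.columns]
    if missing:
        raise SchemaError(f"score gene(s) missing from cohort: {missing}")
    genes = list(score.coefficients)
    w = np.array([score.coefficients[g] for g in genes])
    s = cohort.data[genes].to_numpy(float) @ w
    if threshold is None:
        threshold = float(np.median(s))
    score.threshold = threshold
    groups = np.where(s >= threshold, "high", "low")
    index = cohort.data["patient_id"]
    return (
        pd.Series(s, index=index, name="score"),
        pd.Series(groups, index=index, name="risk_group"),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, concordance
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float  # months; inf when never reaching 0.5

    @property
    def median_label(self) -> str:
        return "not reached" if np.isinf(self.median_survival) else f"{self.median_survival:g}"


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate (delegates to lifelines)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        at_risk=table["at_risk"].to_numpy(float),
        median_survival=float(kmf.median_survival_time_),
    )


@dataclass
class LogRankResult:
    chi_square: float
    p: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (1 df)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi_square=float(res.test_statistic), p=float(res.p_value))


def concordance_index(predictor, times, events) -> float:
    """Harrell's c for a risk score (higher predictor = higher risk).

    Computed over comparable pairs; predictor ties count 0.5.
    """
    predictor = np.asarray(predictor, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise ValueError("no events: no comparable pairs")
    return float(_ll_concordance(times, -predictor, events))


def optimism_corrected_cindex(
    cohort: CohortTable,
    features: list[str] | tuple[str, ...],
    B: int = 500,
    seed: int = 0,
    ties: str = "breslow",
    max_fail_fraction: float = 0.2,
) -> tuple[float, float]:
    """Harrell's bootstrap optimism correction of the apparent c-index.

    Per replicate, the model is refit on a bootstrap sample; optimism_b is
    the bootstrap-sample c minus the c of the same model on the original
    data; corrected = apparent - mean(optimism).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    features = tuple(features)
    model = fit_cox(cohort, features, ties=ties)
    apparent = concordance_index(model.risk_score(cohort), cohort.times, cohort.events)
    rng = np.random.default_rng(seed)
    n = cohort.n_patients
    optimism = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sub = CohortTable(
            data=cohort.data.iloc[idx].assign(patient_id=[f"B{i:05d}" for i in range(n)]),
            gene_cols=cohort.gene_cols,
            clinical_cols=cohort.clinical_cols,
        )
        try:
            m_b = fit_cox(sub, features, ties=ties)
        except (np.linalg.LinAlgError, ConvergenceError, ValueError):
            failures += 1
            continue
        c_boot = concordance_index(m_b.risk_score(sub), sub.times, sub.events)
        c_orig = concordance_index(m_b.risk_score(cohort), cohort.times, cohort.events)
        optimism.append(c_boot - c_orig)
    if failures > max_fail_fraction * B:
        raise RuntimeError(f"{failures}/{B} optimism replicates failed")
    corrected = apparent - float(np.mean(optimism))
    return apparent, corrected


# ---------------------------------------------------------------------------
# Risk-group clinical comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test: str  # "t_test" or "chi_square"
    group_summary: dict[str, str]
    statistic: float
    p: float


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variability
        return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_risk_groups(
    cohort: CohortTable,
    grouping: pd.Series,
    variables: list[str],
    continuous: set[str] | None = None,
) -> list[GroupComparison]:
    """Welch t-test for continuous variables, chi-square (no continuity
    correction) for categorical ones, across the two risk groups."""
    g = np.asarray(grouping)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, found {levels}")
    if continuous is None:
        continuous = {
            v for v in variables
            if np.issubdtype(cohort.data[v].dtype, np.floating) or cohort.data[v].nunique() > 10
        }
    out = []
    for var in variables:
        col = cohort.data[var]
        if var in continuous:
            a = col.to_numpy(float)[g == levels[0]]
            b = col.to_numpy(float)[g == levels[1]]
            t, p = _welch_p(a, b)
            summary = {
                str(levels[0]): f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                str(levels[1]): f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
            }
            out.append(GroupComparison(var, "t_test", summary, t, p))
        else:
            table = pd.crosstab(g, col)
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                raise ValueError(f"empty row/column in contingency table for {var!r}")
            if table.shape[1] < 2:
                # a single observed category carries no contrast
                out.append(GroupComparison(var, "chi_square", {}, 0.0, 1.0))
                continue
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            summary = {
                str(lv): " / ".join(
                    f"{table.loc[lv, c] / table.loc[lv].sum():.1%} {c}" for c in table.columns
                )
                for lv in table.index
            }
            out.append(GroupComparison(var, "chi_square", summary, float(chi2), float(p)))
    return out
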