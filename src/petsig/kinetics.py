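"""Radiotracer uptake kinetics from cell-culture time-activity curves.

Two kinetic analyses are implemented.  Irreversible glucose-analogue uptake
is linearised with the closed-system Patlak plot: with medium(t) = 1 -
cells(t) in fraction-of-dose units,

    cells(t)/medium(t) = a * [integral_0^t medium ds] / medium(t) + b,

so an ordinary least-squares line through the transformed points recovers
the accumulation rate constant ``a`` (its product with the medium glucose
concentration estimates glucose consumption).  Saturable receptor binding
is fitted with the one-phase association model A(t) = Amax * (1 - e^{-kt}),
where Amax reflects the number of accessible binding sites and k the
association rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import TimeActivityCurve

__all__ = [
    "PatlakResult",
    "OnePhaseResult",
    "KineticComparison",
    "normalize_counts",
    "patlak_transform",
    "patlak_fit",
    "one_phase_fit",
    "compare_kinetics",
]


def normalize_counts(
    raw_counts,
    efficiency: float,
    administered: float,
    time=None,
    meta: dict | None = None,
) -> TimeActivityCurve:
    """Convert raw detector counts to fraction-of-administered-dose units.

    activity(t) = raw(t) / efficiency / administered, where ``efficiency``
    is the calibrated detector recovery (~0.03) and ``administered`` the
    total source emission in the same counts units.
    """
    raw = np.asarray(raw_counts, float)
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must lie in (0, 1]")
    if administered <= 0:
        raise ValueError("administered dose must be positive")
    if time is None:
        time = np.arange(len(raw), dtype=float)
    meta = dict(meta or {})
    meta.setdefault("detector_efficiency", efficiency)
    return TimeActivityCurve(time=np.asarray(time, float), activity=raw / efficiency / administered, meta=meta)


# ---------------------------------------------------------------------------
# Patlak graphical analysis (closed system)
# ---------------------------------------------------------------------------

@dataclass
class PatlakResult:
    slope_a: float  # accumulation rate constant, per minute
    intercept_b: float
    r_squared: float
    glucose_consumption: float  # mM per minute (slope * medium glucose)


def patlak_transform(curve: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Closed-system Patlak coordinates.

    x(t) = [integral_0^t medium ds] / medium(t) (trapezoid rule at native
    sampling), y(t) = cells(t)/medium(t); the t = 0 point is (0, 0) when the
    curve starts at zero retention.
    """
    medium = 1.0 - curve.activity
    if np.any(medium <= 0):
        raise ValueError("medium activity depleted to zero; Patlak transform undefined")
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (medium[1:] + medium[:-1]) * np.diff(curve.time))]
    )
    x = integral / medium
    y = curve.activity / medium
    return x, y


def patlak_fit(curve: TimeActivityCurve, t_start: float = 0.0) -> PatlakResult:
    """OLS line through the Patlak-transformed points with t >= t_start."""
    x, y = patlak_transform(curve)
    mask = curve.time >= t_start
    if mask.sum() < 3:
        raise ValueError("need at least three points after t_start")
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0:
        raise ValueError("degenerate Patlak abscissa (all x equal)")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    glucose = curve.meta.get("glucose_mM", 5.5)
    return PatlakResult(
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=r2,
        glucose_consumption=float(res.slope) * float(glucose),
    )


# ---------------------------------------------------------------------------
# One-phase association
# ---------------------------------------------------------------------------

@dataclass
class OnePhaseResult:
    amax: float  # fraction of dose; asymptotic plateau (accessible sites)
    k: float  # per minute; association rate constant
    r_squared: float


def _one_phase(t, amax, k):
    return amax * (1.0 - np.exp(-k * t))


def one_phase_fit(curve: TimeActivityCurve, init_strategy: str = "geometry") -> OnePhaseResult:
    """Nonlinear least-squares fit of A(t) = Amax * (1 - e^{-kt}).

    Initial values come from the curve geometry: Amax0 is the terminal
    plateau level and k0 = ln2 / t_half from the half-rise time; parameters
    are bounded to Amax in [0, 1] and k in (0, 10] per minute.
    """
    t, A = curve.time, curve.activity
    if len(t) < 4:
        raise ValueError("need at least four points for a one-phase fit")
    if np.any(A < 0):
        raise ValueError("activity must be non-negative")
    overall_slope = np.polyfit(t, A, 1)[0]
    if overall_slope < 0 and A[-1] < A[0]:
        raise ValueError("monotone-decreasing curve cannot follow one-phase association")

    if init_strategy == "geometry":
        amax0 = float(np.clip(np.mean(A[-max(3, len(A) // 20):]), 1e-12, 1.0))
        above = np.flatnonzero(A >= amax0 / 2.0)
        t_half = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] - t[0]) / 10.0
        k0 = float(np.clip(np.log(2.0) / t_half, 1e-6, 10.0))
    else:
        amax0, k0 = float(np.clip(A.max(), 1e-12, 1.0)), 0.05

    popt, _ = optimize.curve_fit(
        _one_phase,
        t,
        A,
        p0=(amax0, k0),
        bounds=([0.0, 1e-9], [1.0, 10.0]),
        xtol=1e-12,
        ftol=1e-12,
        maxfev=20000,
    )
    resid = A - _one_phase(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((A - A.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return OnePhaseResult(amax=float(popt[0]), k=float(popt[1]), r_squared=r2)


# ---------------------------------------------------------------------------
# Replicate-group comparison
# ---------------------------------------------------------------------------

@dataclass
class KineticComparison:
    parameter: str
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    fold_change: float  # group1 / group2
    t_statistic: float
    p: float


def compare_kinetics(fits_group1, fits_group2, parameter: str) -> KineticComparison:
    """Fold change (group1/group2) and Welch t-test on a fitted parameter."""
    v1 = np.array([getattr(f, parameter) for f in fits_group1], float)
    v2 = np.array([getattr(f, parameter) for f in fits_group2], float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("need at least two fits per group")
    if v2.mean() == 0:
        raise ValueError("zero group-2 mean; fold change undefined")
    if np.ptp(v1) == 0 and np.ptp(v2) == 0:
        t, p = (0.0, 1.0) if v1[0] == v2[0] else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(v1, v2, equal_var=False)
    return KineticComparison(
        parameter=parameter,
        mean1=float(v1.mean()),
        sd1=float(v1.std(ddof=1)),
        mean2=float(v2.mean()),
        sd2=float(v2.std(ddof=1)),
        fold_change=float(v1.mean() / v2.mean()),
        t_statistic=float(t),
        p=float(p),
    )
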