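"""Synthetic data generators for the prognostic-signature and kinetics stages.

Two families of generators are provided:

* :func:`simulate_cohort` draws a patient cohort with z-scored gene
  expression and exponential proportional-hazards PFS outcomes, emulating a
  cBioPortal-style primary prostate-cancer export (493 patients, 122 genes,
  ~18.9 % progression rate, four genes with a true prognostic effect).
* :func:`simulate_fdg_curve` / :func:`simulate_psma_curve` draw 120-minute,
  minute-sampled time-activity curves of the kind produced by a rotating-dish
  beta detector: irreversible glucose-analogue accumulation in a closed
  two-pool system, and saturable receptor-ligand association respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CohortTable, TimeActivityCurve

__all__ = [
    "CohortSimConfig",
    "TracerSimConfig",
    "TABLE_EFFECTS",
    "TRACER_PRESETS",
    "simulate_cohort",
    "simulate_fdg_curve",
    "simulate_psma_curve",
    "detector_counts",
    "calibrate_censoring_window",
    "default_cohort_config",
    "child_seed",
]

#: Bootstrap-stabilised log-hazard per z-unit for the four prognostic genes
#: (FOLH1 carries no true effect in the generating model).
TABLE_EFFECTS: dict[str, float] = {
    "PARP2": 0.254,
    "SLC2A4": -0.733,
    "CTH": -0.372,
    "ALDOB": 0.140,
    "FOLH1": 0.0,
}

#: Default target fraction of patients with an observed progression (93/493).
DEFAULT_EVENT_RATE = 0.189


def child_seed(master: int, *path: int) -> int:
    """Deterministic child seed below 2**31 derived from a master seed.

    Children are spawned via :class:`numpy.random.SeedSequence` with the path
    as spawn key, so (stage, replicate) pairs never collide.
    """
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class CohortSimConfig:
    """Generating model for a synthetic survival cohort.

    ``causal_effects`` maps gene name to log-hazard per z-unit; all other
    genes are pure noise.  Survival times are exponential with hazard
    ``baseline_hazard * exp(linear predictor)`` and censoring is uniform
    administrative on (0, censoring_window].
    """

    n_patients: int = 493
    n_genes: int = 122
    causal_effects: dict[str, float] = field(default_factory=lambda: dict(TABLE_EFFECTS))
    baseline_hazard: float = 0.004  # events per month at z = 0
    censoring_window: float | None = None  # months; None => calibrate to event rate
    target_event_rate: float = DEFAULT_EVENT_RATE
    clinical_effects: dict[str, float] = field(default_factory=dict)
    correlation: float = 0.0  # equi-correlation between gene z-scores
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_genes < len(self.causal_effects):
            raise ValueError("n_genes must cover all causal_effects genes")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_window is not None and self.censoring_window <= 0:
            raise ValueError("censoring_window must be positive")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must lie in [0, 1)")
        unknown = set(self.clinical_effects) - set(CLINICAL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown clinical covariate(s): {sorted(unknown)}")

    def gene_names(self) -> list[str]:
        """Planted genes first by convention, then numbered fillers; the
        returned list is alphabetically sortable and stable."""
        planted = sorted(self.causal_effects)
        n_fill = self.n_genes - len(planted)
        fillers = [f"G{i:03d}" for i in range(1, n_fill + 1)]
        return sorted(planted + fillers)


#: Clinical covariates emitted with every cohort; marginals mirror the
#: descriptive statistics of a primary prostate-cancer surgical series.
CLINICAL_COLUMNS = ("age_years", "race_white", "nonacinar", "t3_plus", "n1")


def _draw_clinical(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_years": rng.normal(61.0, 6.8, n).round(1),
            "race_white": rng.binomial(1, 0.955, n),
            "nonacinar": rng.binomial(1, 0.015, n),
            "t3_plus": rng.binomial(1, 0.31, n),
            "n1": rng.binomial(1, 0.093, n),
        }
    )


def _clinical_lp(clin: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(clin))
    for name, gamma in effects.items():
        col = clin[name].to_numpy(float)
        if name == "age_years":  # effects are per SD for the continuous covariate
            col = (col - 61.0) / 6.8
        lp += gamma * col
    return lp


def _expected_event_rate(window: float, lam0: float, lp: np.ndarray) -> float:
    """P(T < C) for exponential T with hazard lam0*exp(lp), C ~ U(0, window]."""
    u = lam0 * np.exp(lp) * window
    with np.errstate(over="ignore"):
        frac = np.where(u > 1e-8, (1.0 - np.exp(-u)) / np.where(u > 0, u, 1.0), 1.0 - u / 2.0)
    return float(np.mean(1.0 - frac))


def calibrate_censoring_window(config: CohortSimConfig, n_draws: int = 100_000) -> float:
    """Censoring window giving the target expected event rate, by bisection.

    The expectation is taken over a fixed internal Monte-Carlo sample of the
    linear predictor (same equi-correlated gene structure and clinical
    covariates as :func:`simulate_cohort`), so the result is deterministic
    for a given config and independent of the cohort seed.
    """
    rng = np.random.default_rng(987_654_321)
    betas = np.array([config.causal_effects[g] for g in sorted(config.causal_effects)])
    rho = config.correlation
    # equi-correlated gene z-scores: z = sqrt(rho)*u + sqrt(1-rho)*eps
    shared = rng.standard_normal(n_draws)
    eps = rng.standard_normal((n_draws, len(betas)))
    z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * eps
    lp = z @ betas
    if config.clinical_effects:
        clin = _draw_clinical(rng, n_draws)
        lp = lp + _clinical_lp(clin, config.clinical_effects)

    target = config.target_event_rate
    lo, hi = 1e-3, 1.0
    while _expected_event_rate(hi, config.baseline_hazard, lp) < target:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("censoring calibration failed to bracket the target rate")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _expected_event_rate(mid, config.baseline_hazard, lp) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * hi:
            break
    return 0.5 * (lo + hi)


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    """The study-condition cohort: 493 patients, 122 genes, four planted
    prognostic effects, censoring calibrated to an 18.9 % event rate."""
    cfg = CohortSimConfig(seed=seed)
    cfg.censoring_window = calibrate_censoring_window(cfg)
    return cfg


def simulate_cohort(config: CohortSimConfig) -> CohortTable:
    """Draw a synthetic cohort under an exponential proportional-hazards model.

    Gene z-scores are standard normal (equi-correlated at
    ``config.correlation``); the linear predictor is the sum of gene and
    clinical effects; event = progression observed before the uniform
    administrative censoring time.  Deterministic for a fixed config.
    """
    genes = config.gene_names()
    unknown = set(config.causal_effects) - set(genes)
    if unknown:
        raise ValueError(f"causal_effects refer to unknown gene(s): {sorted(unknown)}")
    window = config.censoring_window
    if window is None:
        window = calibrate_censoring_window(config)

    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_genes
    rho = config.correlation
    if rho > 0:
        shared = rng.standard_normal(n)
        z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * rng.standard_normal((n, p))
    else:
        z = rng.standard_normal((n, p))
    expr = pd.DataFrame(z, columns=genes)

    clin = _draw_clinical(rng, n)
    beta = np.array([config.causal_effects.get(g, 0.0) for g in genes])
    lp = z @ beta + _clinical_lp(clin, config.clinical_effects)

    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, window, n)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    data = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "time_months": observed,
            "event": event,
        }
    )
    data = pd.concat([data, clin, expr], axis=1)
    return CohortTable(data=data, gene_cols=tuple(genes), clinical_cols=CLINICAL_COLUMNS)


# ---------------------------------------------------------------------------
# Time-activity curves
# ---------------------------------------------------------------------------

#: Kinetic presets.  FDG rates are the accumulation constants of the closed
#: two-pool system; the PSMA pairs keep the 15-fold plateau and 5-fold rate
#: ratios between the low- and high-passage cultures while staying far below
#: dose saturation.
TRACER_PRESETS: dict[str, dict[str, float]] = {
    "FDG-LNCaP30": {"accumulation_rate_a": 1.4e-7},
    "FDG-LNCaP80": {"accumulation_rate_a": 2.7e-7},
    "PSMA-LNCaP30": {"amax": 0.045, "k": 0.040},
    "PSMA-LNCaP80": {"amax": 0.003, "k": 0.008},
}


@dataclass
class TracerSimConfig:
    """Generating model for one time-activity curve.

    For FDG-like tracers the forward model is the closed-system mass balance
    d(cells)/dt = a * medium(t) with medium(t) = 1 - cells(t) in
    fraction-of-dose units; for PSMA-like tracers it is the one-phase
    association A(t) = amax * (1 - exp(-k t)).  Multiplicative Gaussian
    measurement noise of coefficient of variation ``noise_cv`` is applied to
    every sample.
    """

    preset: str = "custom"
    duration: float = 120.0  # minutes
    sampling: float = 1.0  # minutes between samples
    accumulation_rate_a: float | None = None  # per minute (FDG)
    amax: float | None = None  # fraction of dose (PSMA)
    k: float | None = None  # per minute (PSMA)
    noise_cv: float = 0.01
    detector_efficiency: float = 0.03
    glucose_mM: float = 5.5
    medium_volume_ml: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset != "custom":
            if self.preset not in TRACER_PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            for key, val in TRACER_PRESETS[self.preset].items():
                if getattr(self, key) is None:
                    setattr(self, key, val)
        if self.duration <= 0 or self.sampling <= 0:
            raise ValueError("duration and sampling must be positive")
        if abs(self.duration / self.sampling - round(self.duration / self.sampling)) > 1e-9:
            raise ValueError("duration must be an integer multiple of sampling")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not (0 < self.detector_efficiency <= 1):
            raise ValueError("detector_efficiency must lie in (0, 1]")
        if self.amax is not None and not (0 <= self.amax <= 1):
            raise ValueError("amax must lie in [0, 1] (fraction of dose)")
        if self.k is not None and self.k < 0:
            raise ValueError("k must be non-negative")
        if self.accumulation_rate_a is not None and self.accumulation_rate_a < 0:
            raise ValueError("accumulation_rate_a must be non-negative")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sampling))
        return np.arange(n + 1) * self.sampling


def _apply_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values
    noisy = values * (1.0 + cv * rng.standard_normal(values.shape))
    return np.clip(noisy, 0.0, 1.0)


def _curve_meta(config: TracerSimConfig, tracer: str) -> dict:
    return {
        "tracer": tracer,
        "preset": config.preset,
        "glucose_mM": config.glucose_mM,
        "medium_volume_ml": config.medium_volume_ml,
        "detector_efficiency": config.detector_efficiency,
        "noise_cv": config.noise_cv,
        "seed": config.seed,
    }


def simulate_fdg_curve(config: TracerSimConfig) -> TimeActivityCurve:
    """Irreversible accumulation in a closed two-pool system.

    The mass balance d(cells)/dt = a * (1 - cells) has the exact solution
    cells(t) = 1 - exp(-a t), so medium + cells conserve the administered
    dose at every sample before noise.
    """
    a = config.accumulation_rate_a
    if a is None:
        raise ValueError("accumulation_rate_a is required for an FDG-like curve")
    t = config.time_grid()
    cells = 1.0 - np.exp(-a * t)
    rng = np.random.default_rng(config.seed)
    activity = _apply_noise(cells, config.noise_cv, rng)
    return TimeActivityCurve(time=t, activity=activity, meta=_curve_meta(config, "FDG"))


def simulate_psma_curve(config: TracerSimConfig) -> TimeActivityCurve:
    """Saturable receptor-ligand association A(t) = amax * (1 - exp(-k t))."""
    if config.amax is None or config.k is None:
        raise ValueError("amax and k are required for a PSMA-like curve")
    t = config.time_grid()
    ideal = config.amax * (1.0 - np.exp(-config.k * t))
    rng = np.random.default_rng(config.seed)
    activity = _apply_noise(ideal, config.noise_cv, rng)
    return TimeActivityCurve(time=t, activity=activity, meta=_curve_meta(config, "PSMA"))


def detector_counts(curve: TimeActivityCurve, administered: float) -> np.ndarray:
    """Raw counts the beta detector would record for a curve.

    ``administered`` is the total source emission in counts-equivalent; the
    detector recovers ``detector_efficiency`` of the activity in the dish.
    Inverse of :func:`petsig.kinetics.normalize_counts`.
    """
    eff = curve.meta.get("detector_efficiency", 0.03)
    return curve.activity * eff * administered
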