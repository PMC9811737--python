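"""End-to-end orchestration of the prognostic-signature and kinetics runs.

``run_pipeline`` chains: cohort simulation/loading -> event labelling ->
stratified splits -> Random Forest and hybrid-Lasso rankings -> rank
aggregation -> top-k consensus -> bootstrap-stabilised Cox on the consensus
genes -> genetic score + median split -> Kaplan-Meier, log-rank and
(optimism-corrected) c-index -> clinical risk-group comparison.  All outputs
are deterministic functions of the manifest (config + master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CohortTable
from .io import read_cohort, write_cohort, write_curve, write_json
from .ranking import consensus_ranking
from .simulate import (
    CohortSimConfig,
    TracerSimConfig,
    child_seed,
    default_cohort_config,
    simulate_cohort,
    simulate_fdg_curve,
    simulate_psma_curve,
)
from .survival import (
    apply_score,
    bootstrap_cox,
    build_genetic_score,
    compare_risk_groups,
    km_estimate,
    logrank_test,
    optimism_corrected_cindex,
)
from .kinetics import compare_kinetics, one_phase_fit, patlak_fit

log = logging.getLogger("petsig")

__all__ = ["PipelineConfig", "run_pipeline", "run_kinetics"]


@dataclass
class PipelineConfig:
    """Everything a signature run needs; serialisable to/from YAML."""

    cohort_path: str | None = None  # load instead of simulate when set
    cohort_sim: dict = field(default_factory=dict)  # CohortSimConfig overrides
    n_splits: int = 100
    k: int = 10
    n_trees: int = 500
    cv_folds: int = 5
    rf_label_mode: str = "recorded"
    B: int = 500
    alpha: float = 0.05
    ties: str = "breslow"
    force_include: tuple[str, ...] = ()
    compute_optimism: bool = True
    seed: int = 0
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_splits <= 0 or self.B <= 0:
            raise ValueError("n_splits and B must be positive")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)

    def manifest(self) -> dict:
        cfg = asdict(self)
        cfg["force_include"] = list(self.force_include)
        blob = json.dumps(cfg, sort_keys=True)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "petsig_version": __version__,
        }


def _load_or_simulate(config: PipelineConfig) -> CohortTable:
    if config.cohort_path is not None:
        log.info("loading cohort from %s", config.cohort_path)
        return read_cohort(config.cohort_path)
    if config.cohort_sim:
        sim = CohortSimConfig(**{**config.cohort_sim, "seed": child_seed(config.seed, 0)})
    else:
        sim = default_cohort_config(seed=child_seed(config.seed, 0))
    cohort = simulate_cohort(sim)
    log.info("simulated cohort: n=%d, %d genes, event rate %.3f",
             cohort.n_patients, len(cohort.gene_cols), cohort.event_rate)
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full signature pipeline; returns and writes the bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_simulate(config)
    write_cohort(cohort, outdir / "cohort.tsv", sidecar=config.manifest())

    rank_out = consensus_ranking(
        cohort,
        n_splits=config.n_splits,
        k=config.k,
        n_trees=config.n_trees,
        cv_folds=config.cv_folds,
        rf_label_mode=config.rf_label_mode,
        seed=child_seed(config.seed, 10),
    )
    consensus = rank_out["consensus"]
    log.info("consensus top-%d intersection: %s", config.k, list(consensus.genes))
    ranking_df = pd.DataFrame(
        {
            "gene": list(rank_out["agg_rf"].mean_rank.index),
            "mean_rank_rf": rank_out["agg_rf"].mean_rank.to_numpy(),
            "mean_rank_lasso": rank_out["agg_lasso"].mean_rank.to_numpy(),
        }
    ).sort_values("gene")
    ranking_df.to_csv(outdir / "rankings.tsv", sep="\t", index=False)
    write_json({"k": consensus.k, "genes": list(consensus.genes)}, outdir / "consensus.json")

    if not consensus.genes:
        raise RuntimeError("empty consensus set; cannot build a Cox model")
    features = list(consensus.genes) + [g for g in config.force_include if g not in consensus.genes]
    model = bootstrap_cox(cohort, features, B=config.B, seed=child_seed(config.seed, 20), ties=config.ties)
    if config.compute_optimism:
        apparent, corrected = optimism_corrected_cindex(
            cohort, features, B=config.B, seed=child_seed(config.seed, 21), ties=config.ties
        )
        model.cindex_apparent, model.cindex_corrected = apparent, corrected
    write_json(model.as_dict(), outdir / "cox_model.json")

    score = build_genetic_score(model, alpha=config.alpha, force_include=config.force_include)
    scores, groups = apply_score(score, cohort)
    pd.DataFrame({"patient_id": cohort.data["patient_id"], "score": scores.to_numpy(),
                  "risk_group": groups.to_numpy()}).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    write_json(
        {"coefficients": score.coefficients, "threshold": score.threshold,
         "formula": score.formula_text},
        outdir / "genetic_score.json",
    )

    hi = groups.to_numpy() == "high"
    km_rows = []
    km_curves = {}
    for name, mask in (("low", ~hi), ("high", hi)):
        km = km_estimate(cohort.times[mask], cohort.events[mask])
        km_curves[name] = km
        km_rows.append(pd.DataFrame({
            "group": name, "time_months": km.event_times,
            "survival": km.survival, "at_risk": km.at_risk,
        }))
    pd.concat(km_rows).to_csv(outdir / "km_curves.csv", index=False)
    lr = logrank_test(cohort.times[~hi], cohort.events[~hi], cohort.times[hi], cohort.events[hi])
    write_json({"chi_square": lr.chi_square, "p": lr.p,
                "median_low": km_curves["low"].median_label,
                "median_high": km_curves["high"].median_label}, outdir / "logrank.json")

    comparisons = compare_risk_groups(cohort, groups, list(cohort.clinical_cols))
    pd.DataFrame([{"variable": c.variable, "test": c.test, "statistic": c.statistic,
                   "p": c.p, **{f"group_{k}": v for k, v in c.group_summary.items()}}
                  for c in comparisons]).to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False)

    write_json(config.manifest(), outdir / "manifest.json")
    return {
        "cohort": cohort,
        "ranking": rank_out,
        "model": model,
        "score": score,
        "scores": scores,
        "groups": groups,
        "km": km_curves,
        "logrank": lr,
        "comparisons": comparisons,
    }


def simulate_preset_curves(preset: str, n_replicates: int = 6, seed: int = 0,
                           noise_cv: float = 0.01) -> list:
    """Replicate time-activity curves for a named tracer preset."""
    curves = []
    for r in range(n_replicates):
        cfg = TracerSimConfig(preset=preset, noise_cv=noise_cv, seed=child_seed(seed, 5, r))
        if preset.startswith("FDG"):
            curves.append(simulate_fdg_curve(cfg))
        else:
            curves.append(simulate_psma_curve(cfg))
    return curves


def run_kinetics(
    groups: dict[str, list],
    outdir: str | Path = "results/kinetics",
) -> dict:
    """Fit every curve in each replicate group and compare the two groups.

    ``groups`` maps group name -> list of TimeActivityCurve; all curves in a
    group (and across the two groups) must share the tracer type.
    """
    if len(groups) != 2:
        raise ValueError("expected exactly two replicate groups")
    for name, curves in groups.items():
        if not curves:
            raise ValueError(f"empty curve group {name!r}")
    tracers = {c.meta.get("tracer", "?") for curves in groups.values() for c in curves}
    if len(tracers) != 1:
        raise ValueError(f"mixed tracer types in one comparison: {sorted(tracers)}")
    tracer = tracers.pop()

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fits: dict[str, list] = {}
    rows = []
    for name, curves in groups.items():
        fits[name] = []
        for i, curve in enumerate(curves):
            if tracer == "FDG":
                fit = patlak_fit(curve)
                rows.append({"group": name, "replicate": i, "slope_a": fit.slope_a,
                             "intercept_b": fit.intercept_b, "r_squared": fit.r_squared,
                             "glucose_consumption": fit.glucose_consumption})
            else:
                fit = one_phase_fit(curve)
                rows.append({"group": name, "replicate": i, "amax": fit.amax,
                             "k": fit.k, "r_squared": fit.r_squared})
            fits[name].append(fit)
    pd.DataFrame(rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    g1, g2 = list(groups)
    params = ["slope_a", "glucose_consumption"] if tracer == "FDG" else ["amax", "k"]
    comparisons = {p: compare_kinetics(fits[g1], fits[g2], p) for p in params}
    write_json(
        {p: {"fold_change": c.fold_change, "mean_" + g1: c.mean1, "sd_" + g1: c.sd1,
             "mean_" + g2: c.mean2, "sd_" + g2: c.sd2, "p": c.p}
         for p, c in comparisons.items()},
        outdir / "comparisons.json",
    )
    return {"fits": fits, "comparisons": comparisons, "tracer": tracer}
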