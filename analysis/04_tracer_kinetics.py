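#!/usr/bin/env python
"""In-vitro tracer kinetics on simulated time-activity curves.

Simulates six replicate 120-minute curves per culture condition for both
tracers, then:

* FDG (irreversible uptake): closed-system Patlak analysis; reports the
  accumulation rate constant per culture and the LNCaP-80/LNCaP-30 fold
  change (~2, the "almost halved" rate seen the other way round).
* PSMA (saturable binding): one-phase association fits; reports the Amax
  fold change (~15, accessible binding sites) and k fold change (~5,
  association rate) between LNCaP-30 and LNCaP-80, plus fit quality.
"""

import argparse
from pathlib import Path

from petsig.pipeline import run_kinetics, simulate_preset_curves

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=6)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

print("== FDG: Patlak accumulation rate ==")
fdg = run_kinetics(
    {
        "LNCaP-80": simulate_preset_curves("FDG-LNCaP80", args.replicates, args.seed),
        "LNCaP-30": simulate_preset_curves("FDG-LNCaP30", args.replicates, args.seed + 1),
    },
    outdir=args.outdir / "kinetics_fdg",
)
c = fdg["comparisons"]["slope_a"]
print(f"slope a: LNCaP-80 {c.mean1:.3g} +/- {c.sd1:.2g} min^-1, "
      f"LNCaP-30 {c.mean2:.3g} +/- {c.sd2:.2g} min^-1")
print(f"fold change (80/30): {c.fold_change:.2f}, Welch p {c.p:.2g}")
g = fdg["comparisons"]["glucose_consumption"]
print(f"glucose consumption (5.5 mM medium): "
      f"{g.mean1:.3g} vs {g.mean2:.3g} mM/min")

print("\n== PSMA: one-phase association ==")
psma = run_kinetics(
    {
        "LNCaP-30": simulate_preset_curves("PSMA-LNCaP30", args.replicates, args.seed + 2),
        "LNCaP-80": simulate_preset_curves("PSMA-LNCaP80", args.replicates, args.seed + 3),
    },
    outdir=args.outdir / "kinetics_psma",
)
for name, label in (("amax", "Amax (accessible sites)"), ("k", "k (association rate)")):
    c = psma["comparisons"][name]
    print(f"{label}: LNCaP-30 {c.mean1:.3g} +/- {c.sd1:.2g}, "
          f"LNCaP-80 {c.mean2:.3g} +/- {c.sd2:.2g}; "
          f"fold change {c.fold_change:.1f}, Welch p {c.p:.2g}")
r2 = [f.r_squared for fits in psma["fits"].values() for f in fits]
print(f"one-phase fit R^2 range: {min(r2):.4f} - {max(r2):.4f} "
      f"(> 0.95 in all replicates)")
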