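#!/usr/bin/env python
"""Point-estimate counterfactual trajectories for the full regime battery.

One Step-1 fit feeds every regime: never / always-all / each single
component / audit+feedback / natural course.  Prints wave-4 means and the
always-vs-never and component-vs-never contrasts in percentage points, and
compares each against the generator's structural ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

import pegf

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = pegf.SyntheticConfig()
panel = pegf.generate_panel(cfg, seed=args.seed)
specs = panel.specs
fitted = pegf.fit_models(panel)
regimes = pegf.default_regimes(specs, panel.T)

results = {r.name: pegf.run_gformula(panel, specs, r, seed=args.seed,
                                     fitted=fitted) for r in regimes}
traj = pd.concat([res.to_frame() for res in results.values()],
                 ignore_index=True)
traj.to_csv(args.out / "regime_trajectories.csv", index=False)

truth = pegf.truth_table(cfg, regimes, n_large=100_000, seed=args.seed)
truth4 = truth[truth.wave == panel.T].set_index("regime")["true_mean"]

rows = []
for name, res in results.items():
    est = res.means[-1] * 100
    diff = pegf.contrast_regimes(results["never"], res)
    rows.append((name, round(est, 2), round(truth4[name] * 100, 2),
                 round(diff, 2)))
table = pd.DataFrame(rows, columns=["regime", "estimated_wave4_pct",
                                    "true_wave4_pct", "vs_never_pp"])
table.to_csv(args.out / "regime_means.csv", index=False)
print(table.to_string(index=False))
print("\nreading: the estimated wave-4 column should track the truth column "
      "(estimator SD is roughly 1.5pp on a single cohort), and the "
      "single-component contrasts should rank teacher > mti > "
      "audit ~ feedback ~ 0.")
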