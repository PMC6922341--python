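"""Benchmark topology recovery across series lengths and noise levels.

For each (length, perturbation SD) condition this simulates fresh cusp
series, reruns the whole recovery pipeline, and summarizes how well the
extracted set points reproduce the generating equilibrium surface: the Cobb
pseudo-R-square of a fitted cusp density (fold-aware) against the multiple
R-square of a plane (fold-blind), plus the attractor/repeller/transient
census.

With the default five replicates per condition this takes a couple of
minutes; raise --reps for tighter means.

Run:  python examples/monte_carlo_benchmark.py [--reps 5]
"""

import argparse

from dyntopo import reports_to_table, run_monte_carlo

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--reps", type=int, default=5)
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

conditions = [(250, 0.05), (1000, 0.05), (1000, 0.15)]
reports = run_monte_carlo(conditions, reps=args.reps, seed=args.seed, progress=True)
table = reports_to_table(reports)

cols = ["n", "sd_error", "reps", "failures", "prop_error_mean",
        "attractors_mean", "repellers_mean", "transients_mean",
        "linear_r2_mean", "cusp_r2_mean"]
print()
print(table[cols].round(3).to_string(index=False))
print("\nReading: the cusp fit should beat the plane wherever the fold is"
      "\nresolvable, and the margin should shrink as perturbation noise grows.")
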