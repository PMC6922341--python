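"""Recover the folded equilibrium surface of a stochastic cusp from one series.

A single simulated trajectory explores the cusp's control plane because the
asymmetry (A) and bifurcation (B) parameters are redrawn uniformly at every
step.  A quantile regression forest fitted to the one-step changes then lets
us ask, for every (Y, A, B) grid coordinate, whether "no change" is a
plausible prediction — and the flagged coordinates trace out the equilibrium
surface -y^3 + B*y + A = 0, fold and all.

Run:  python examples/cusp_recovery.py            (~1 minute)
Outputs go to examples/output/.
"""

from pathlib import Path

import numpy as np

from dyntopo import (
    CuspConfig,
    ForestParams,
    classify_setpoints,
    cobb_r2,
    count_by_class,
    cusp_default_grid,
    find_setpoints,
    fit_cusp_mle,
    fit_forest,
    linear_r2,
    make_diff_frame,
    prop_error,
    setpoints_to_frame,
    simulate_cusp,
)
from dyntopo.plotting import plot_setpoints_3d

OUT = Path(__file__).parent / "output"
OUT.mkdir(exist_ok=True)

# 1. simulate: 1000 observations, perturbation SD 0.05 (about 12% of the
#    total variability in Y, mimicking a modestly noisy measured system)
series = simulate_cusp(CuspConfig(n=1000, sd_e=0.05, seed=7))
print(f"simulated {len(series.y)} steps; noise share of sd(Y): "
      f"{prop_error(series):.3f}")

# 2. difference frame: outcome d_y = Y[t+1]-Y[t], predictors y, a, b
frame = make_diff_frame(series.to_frame(), modeled=["y"], controls=["a", "b"])

# 3. quantile regression forest for the change outcome
model = fit_forest(frame, "d_y", ForestParams(n_trees=500, seed=7))

# 4. flag set points: grid coordinates where the 40-60% interval of
#    predicted change contains zero
grid = cusp_default_grid()
setpoints = find_setpoints([model], grid, q_low=0.4, q_high=0.6)
print(f"{len(setpoints)} set points flagged out of {len(grid)} grid points")

# 5. classify each set point by +/-0.05 probes of the predicted change
probes = classify_setpoints([model], setpoints, delta=0.05, grid_step=0.05)
print("class counts:", count_by_class(probes))

# 6. score the recovered cloud against the known generating surface:
#    a plane (linear R^2) vs the cusp density (Cobb pseudo-R^2)
tab = setpoints_to_frame(setpoints)
tab["dynamics_class"] = [p.label for p in probes]
Y, A, B = (tab[c].to_numpy() for c in ("y", "a", "b"))
fit = fit_cusp_mle(Y, A, B)
print(f"linear R^2 = {linear_r2(Y, A, B):.3f}   "
      f"Cobb pseudo-R^2 = {cobb_r2(Y, A, B, fit):.3f}")
print(f"fitted alpha = {fit.alpha_coefs[0]:+.2f} {fit.alpha_coefs[1]:+.2f}*A, "
      f"beta = {fit.beta_coefs[0]:+.2f} {fit.beta_coefs[1]:+.2f}*B")

# 7. render the recovered sheet in (A, B, Y) space
png = plot_setpoints_3d(tab, OUT / "cusp_setpoints.png")
print(f"wrote {png}")

# ground truth for comparison: how far is each set point from the nearest
# real root of -y^3 + B y + A?
def nearest_root(y, a, b):
    r = np.roots([-1.0, 0.0, b, a])
    r = r[np.abs(r.imag) < 1e-8].real
    return r[np.argmin(np.abs(r - y))]

dist = [abs(y - nearest_root(y, a, b)) for y, a, b in zip(Y, A, B)]
print(f"median |set point - true equilibrium| = {np.median(dist):.3f}")
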