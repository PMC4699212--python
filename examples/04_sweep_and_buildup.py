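"""Parameter sweep and the build-up of segregation.

First a small gamma x eta sweep showing that positive lag-1 duration
correlations are a robust property, not a tuned coincidence; then the
deterministic separation grid and stochastic build-up curves showing how
the normalized separation delta/sigma controls the segregation tendency.
"""

import numpy as np

from streamclass.experiments import sweep_gamma_eta, sweep_aggregates
from streamclass.phase_stats import buildup_curve, deterministic_grid

table = sweep_gamma_eta(grid_size=6, n_phases=200, max_elements=60_000, seed=0)
agg = sweep_aggregates(table)
print(f"sweep: {agg['n_switching']}/{agg['n_runs']} runs switched")
print(f"mean within-run lag-1 correlation: I->S {agg['lag1_IS']['mean']:.3f} "
      f"({agg['lag1_IS']['n_positive']}/{agg['lag1_IS']['n']} positive), "
      f"S->I {agg['lag1_SI']['mean']:.3f}")

grid = deterministic_grid([1, 2, 3, 4, 6, 8], [1.0], gamma=0.1, eta_tilde=0.05,
                          beta=0.5, pi2_init=0.001, horizon=40_000)
print("\nsegregation proportion vs separation (deterministic, sigma=1):")
for _, row in grid.iterrows():
    print(f"  delta={row.delta:.0f}: {row.seg_proportion:.2f} of time segregated, "
          f"initial integration {row.init_integration} elements")

curves = buildup_curve([6.0], sigma=4.0, gamma=0.1, eta=0.2, beta=0.5, K=6,
                       pi2_init=0.001, n_runs=100, horizon=500,
                       rng=np.random.default_rng(0))
p = curves[6.0]["p_seg"]
print(f"\nbuild-up (delta/sigma=1.5): P(segregation) rises from "
      f"{p[:10].mean():.2f} (first 10 elements) to {p[-50:].mean():.2f} "
      "(last 50) — integration first, segregation builds up")
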