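"""Phase-duration statistics on synthetic subject reports.

Generates key-press style reports (21 subjects x 6 trials of 4 minutes)
with a known lag-1 correlation injected on the latent log-duration scale,
then runs the full analysis: per-trial normalization, pooled lag
correlations by transition type, and the random-intercept mixed-model test
of the mean per-trial correlation.
"""

import numpy as np

from streamclass import (
    SynthConfig, generate_reports, mixed_model_test,
    per_trial_correlations, pooled_lag_correlation,
)

data = generate_reports(SynthConfig(r=0.3), np.random.default_rng(11))
print(f"{len(data.trials)} trials from {len(data.subjects)} subjects")

for lag, transitions in ((1, ("I->S", "S->I")), (2, ("I->I", "S->S"))):
    for tr in transitions:
        res = pooled_lag_correlation(data, lag, tr)
        print(f"lag {lag} {tr}: rho={res.rho:.3f}, p={res.p:.2g}, n={res.n}")
print("(lag-1 positive and significant; lag-2 near zero, as the AR(1) "
      "construction implies after the log-normal transform)")

per_trial, skipped = per_trial_correlations(data, 1, "I->S")
res = mixed_model_test(per_trial)
print(f"\nmixed model on {res.n_obs} per-trial correlations "
      f"({res.n_groups} subjects, {skipped} trials skipped):")
print(f"mean correlation mu = {res.mu_hat:.3f}, t({res.df:.1f}) = {res.t_stat:.2f}, "
      f"p = {res.p_fixed:.2g}; subject variance {res.subject_variance:.4f} "
      f"(LRT p = {res.p_random:.2f})")
print("the mean per-trial lag-1 correlation is significantly positive")
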