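"""Simultaneous confidence intervals for per-endpoint dose slopes.

Fits marginal logistic models to a simulated five-endpoint study, stacks
them, and prints 95% simultaneous confidence intervals for the slope of each
endpoint alongside the unadjusted marginal intervals.
"""

import numpy as np

from multibin import (
    DesignSpec,
    adjust_mmm,
    fit_logit,
    generate_scenario,
    regression_scenario,
    simultaneous_ci,
    stack,
)

scenario = regression_scenario(
    n=200, n_endpoints=5, pi0=0.15, rho=0.5,
    slopes=[0.20, 0.15, 0.0, 0.0, 0.0],
)
data = generate_scenario(scenario, seed=7)
design = DesignSpec("regression", data.dose)
fits = [fit_logit(data.Y[:, j], design, label=l)
        for j, l in enumerate(data.labels)]

stacked = stack(fits)
res = adjust_mmm(stacked, alpha=0.05)
lo, hi, c = simultaneous_ci(stacked, alpha=0.05)
z = 1.959963984540054

print(f"simultaneous critical value c = {c:.4f} (marginal z = {z:.4f})\n")
print("endpoint  slope     simultaneous 95% CI      marginal 95% CI     p_adj")
for i, lbl in enumerate(stacked.labels):
    b, s = stacked.estimates[i], stacked.se[i]
    print(
        f"{lbl:<9} {b:+.4f}  [{lo[i]:+.4f}, {hi[i]:+.4f}]   "
        f"[{b - z * s:+.4f}, {b + z * s:+.4f}]   {res.p_adj[i]:.4f}"
    )
print(
    "\nThe simultaneous intervals use the max-|z| quantile of the estimated "
    "joint normal\ndistribution, so they are wider than the marginal Wald "
    "intervals but cover all five\nslopes at once with 95% confidence; an "
    "interval excluding 0 corresponds exactly to\nan adjusted p-value below "
    "0.05."
)
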