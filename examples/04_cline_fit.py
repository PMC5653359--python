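"""Fit the 7-parameter sigmoid cline to one trait and test it.

Draws a trait with a known cline (centre 40 m, width 15 m) along a 76 m
transect, fits by maximum likelihood, and tests against the constant-trait
null with the df=5 likelihood-ratio chi-square.
"""

import numpy as np

from wavecline import fit_cline, fit_null, likelihood_ratio_test
from wavecline.cline import ClineParams, cline_mean, cline_sd

true = ClineParams(centre=40.0, width=15.0, mu_crab=1.0, mu_wave=3.0,
                   sd_crab=0.3, sd_wave=0.3, sd_hybrid=0.2)
rng = np.random.default_rng(42)
x = rng.uniform(0, 76, 200)
y = rng.normal(cline_mean(x, true), cline_sd(x, true))

fit = fit_cline(x, y, n_starts=8, seed=0)
null = fit_null(x, y)
lrt = likelihood_ratio_test(fit, null)

print("true vs fitted parameters:")
for name, tv in true.as_dict().items():
    fv = fit.params.as_dict()[name]
    print(f"  {name:>10}: true {tv:7.3f}   fitted {fv:7.3f}")
print(f"\nlnL cline {fit.log_likelihood:.2f} vs null {null.log_likelihood:.2f}")
print(f"LRT: chi2 = {lrt.chi2:.2f}, df = {lrt.df}, p = {lrt.p_value:.3g}")
print("\nA tiny p says the trait really changes along the transect; the "
      "fitted centre/width locate and scale the transition, and the residual "
      "scatter (sd_*) is allowed to differ between ecotype zones.")
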