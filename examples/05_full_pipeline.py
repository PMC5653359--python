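"""Run the whole analysis on a synthetic study with a known causal trait.

Simulates a shore where relative foot area (RFA) causally raises a snail's
dislodgement resistance beyond the shared positional trend, runs the full
pipeline, and prints the residual-correlation table: RFA should surface as
the significant association, other traits should not.
"""

from wavecline.pipeline import RunConfig, run_full_analysis
from wavecline.simulate import ShoreSimConfig

sim = ShoreSimConfig(seed=505, resistance_coupling={"RFA": 25.0})
report = run_full_analysis(RunConfig(sim=sim, seed=505, n_starts=6))

print(f"cohort: {report['manifest']['n_kept']} snails kept, "
      f"{report['manifest']['n_excluded_non_attachers']} non-attachers excluded")

print("\ncline fits (LRT against a constant trait):")
for trait, fit in report["fits"].items():
    print(f"  {trait:>4}: chi2 = {fit['chi2']:7.2f}  p = {fit['p_value']:.2e}  "
          f"centre = {fit['params']['centre']:5.1f} m")

print("\nresidual correlations vs squared flow resistance (BH-corrected):")
print(report["correlations"].to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}"))
print("\nOnly the causally coupled trait (RFA) should stay significant after "
      "the Benjamini-Hochberg correction; every trait still shows a clinal "
      "trend (small LRT p) because all were generated with clines.")
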