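# wavecline

Tools for studying dislodgement-resistance adaptation in intertidal snails
(*Littorina saxatilis*) across a sheltered-to-wave-exposed shore transition.
On such shores the "crab" ecotype (thick-shelled, large) gives way to the
"wave" ecotype (small, large-footed) over tens of metres, and the question
is which traits actually help a snail hold on when water moves fast.
`wavecline` turns field inputs — snail coordinates, shell/foot
morphometrics, flume dislodgement trials on a discrete velocity ladder, and
a fucoid seaweed survey — into that analysis, end to end:

1. **Transect geometry** — fit a Bézier path through the sampled shore and
   project every snail onto it, giving a single position (m) per snail.
2. **Exposure index** — distance-weighted fucoid coverage (weight linear to
   zero at 4 m), an inverse wave-exposure proxy.
3. **Traits** — size-independent ratios (RFA, ROA, RIA, S1, S2, plus SA as
   a size proxy) and the maximum resisted free-stream velocity from
   two-round flume logs, squared (drag ∝ v²) into SFR.
4. **Cline fitting** — for each trait, maximum-likelihood fit of the
   7-parameter sigmoid cline

       mean(x) = μ_crab + (μ_wave − μ_crab) / (1 + e^{−4(x−c)/w})
       sd(x)   = σ_crab(1−f) + σ_wave f + σ_hyb·4f(1−f)

   tested against a constant-trait null by a likelihood-ratio χ² (df = 5).
5. **Associations** — Shapiro-gated Pearson/Spearman correlations between
   trait residuals and SFR residuals with Benjamini–Hochberg correction,
   pairwise residual correlations, and Kruskal–Wallis ecotype comparisons
   for common-garden (lab-raised) snails.
6. **Synthetic studies** — a seeded generator producing complete shores
   with known ground-truth clines, trial logs, fucoid surveys and
   common-garden groups, so every stage is testable without field data.

## Worked example

```python
from wavecline.pipeline import RunConfig, run_full_analysis
from wavecline.simulate import ShoreSimConfig

sim = ShoreSimConfig(seed=505, resistance_coupling={"RFA": 25.0})
report = run_full_analysis(RunConfig(sim=sim, seed=505, n_starts=6))
print(report["correlations"])
```

This simulates a shore where relative foot area causally raises a snail's
true resistance, then runs the full pipeline.  Output (from
`examples/05_full_pipeline.py`):

```
trait  method  coefficient  p_value  n  p_adjusted
  RFA pearson       0.8169   0.0000 71      0.0000
  ROA pearson       0.1361   0.2116 86      0.3173
  RIA pearson       0.1684   0.1211 86      0.2557
   S1 pearson      -0.0812   0.4575 86      0.5490
   S2 pearson       0.0345   0.7523 86      0.7523
   SA pearson      -0.1655   0.1278 86      0.2557
```

Every trait was generated with a spatial cline (all LRT χ² are large), but
after removing each trait's clinal trend only the causally coupled trait,
RFA, remains correlated with resistance residuals — which is precisely the
inference the residual-correlation design is for.  `n` is 71 for RFA
because snails whose foot could not be measured are excluded only from
foot-area analyses.

More narrative scripts live in `examples/` (one per capability); a thin
CLI mirrors the stages: `wavecline simulate|geometry|exposure|traits|fit|associate|run`.

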