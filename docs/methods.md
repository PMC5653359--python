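# Methods

`wavecline` analyses dislodgement-resistance adaptation across a sheltered
("crab") to wave-exposed ("wave") shore transition in intertidal snails.
This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Transect geometry

Sampling coordinates are 2D (x east, y north, metres); height is ignored.
A single Bézier curve of user-chosen control count (default 5) is fitted to
the coordinate cloud, ordered along its first principal axis, and each
snail is projected to its nearest curve point.  The snail's *position* is
the arc length (m) from the curve start; the perpendicular offset is kept
as a diagnostic.

Numerics: evaluation is de Casteljau (numerically stable at any degree);
arc length and projection use a dense lookup table (4,096 samples, about
2 cm spacing on a 76 m shore) with the projection polished by bounded
scalar minimisation over the bracketing table interval, ties resolved to
the smaller parameter.  Curve fitting starts from the chord-length
parameterisation's linear least-squares solution and refines control points
and interior parameter assignments jointly with trust-region least squares;
anchors that lie exactly on a curve of the requested degree are recovered
to machine precision.  A hand-placed shore path is thus replaced by a
deterministic, reproducible fit; absolute positions can differ from any
manually drawn path by a bounded reparameterisation, which shifts cline
centres but not the analysis logic.

## Exposure index

Wave exposure is proxied inversely by fucoid seaweed coverage: a weighted
average of presence/absence quadrat scores with weight max(0, 1 − d/4 m).
The average is over weights (not point count), so it stays in [0, 1].
Distances are straight-line 2D, not along-shore.  A focal point with no
survey support inside the radius returns NaN, never 0 — absence of data is
not absence of fucoids.

## Traits and the resistance ladder

Morphometrics (mm, mm²) reduce to size-independent ratios — RFA = FA/SA,
ROA = OA/SA, RIA = IA/SA, S1 = L1/W1 (globosity), S2 = L2/W2 (lateral
compression) — plus shell area SA as the size proxy.  Missing foot areas
propagate as missing; the snail is kept for all analyses not requiring the
foot.  Flume trials run on the discrete free-stream velocity ladder
0.75/1.42/1.88/2.54/2.69 m/s, three 4 s flushes per level, escalating until
dislodgement, two rounds per snail.  A level counts as resisted only when
all three of its flushes are survived (an intermediate dislodgement credits
the previous level); the snail's score is the best round.  Survivors of the
top level are right-censored at 2.69 m/s.  Snails dislodged within level 1
in both rounds are scored 0 m/s and flagged left-censored so they can enter
the cline fit while remaining identifiable for sensitivity analyses.
Because drag scales with velocity squared, the analysis trait is the
squared maximum velocity (SFR, m²/s²); squaring is monotone, so rank-based
statistics are unaffected.  Snails that never attached in the flume are
excluded from all downstream analyses.

## The cline model

For trait y at position x, with f(x) = 1/(1 + exp(−4(x − c)/w)):

    mean(x) = mu_crab + (mu_wave − mu_crab) · f(x)
    sd(x)   = sd_crab·(1 − f) + sd_wave·f + sd_hybrid·4f(1 − f)

Seven parameters: centre c (m), width w (m; with the 4/w scaling, w is the
inverse of the maximum slope of f), two ecotype means, and three standard
deviations — crab tail, wave tail, and a hybrid-zone excess whose weight
4f(1−f) peaks at 1 in the centre and vanishes in the tails.  The smooth
blend is the default because it keeps the likelihood differentiable; a
piecewise three-zone sd (boundaries at c ± w/2) is available with
`sd_model="piecewise"`.

**Estimation.** Gaussian likelihood, maximised by Nelder–Mead simplex
(function tolerance 1e-8) over an unconstrained reparameterisation.  The
raw likelihood is unbounded at the parameter-space edges: a width
collapsing to zero turns the mean into a step pinned between two
neighbouring snails, and a vanishing-width hybrid zone with an exploding
sd_hybrid absorbs any single observation at unbounded density.  Estimation
therefore happens inside a data-scaled box, as is standard in cline-fitting
software: centre within the sampled position range, width between the
sampling resolution (2·span/n) and twice the span, sds within
[sd_y/100, 5·sd_y] with the hybrid excess in [0, 5·sd_y].  Starting values
are data-driven (end-quartile means, midpoint centre, half-range width,
pooled within-end sd) with 20 seeded jittered restarts by default, plus one
start anchored at the null fit so the nested-model inequality
lnL_cline ≥ lnL_null holds by construction.  Constant-valued data leave
centre and width unidentifiable; the fit is returned flagged rather than
raising.

**Testing.** The null model is a constant Gaussian (closed-form ML: sample
mean, sd with divisor n).  The cline is tested by
χ² = 2(lnL_cline − lnL_null) against chi-square with 5 df; round-off
negatives above −1e-6 clamp to zero, anything lower raises as an
optimisation failure.  Residuals are observed minus fitted mean.

**Calibration caveat.** Under the null, centre and width are unidentified,
so the maximised LRT is a supremum over them and the chi-square(5)
reference is anticonservative.  With thorough multi-start optimisation the
measured null rejection rate at α = 0.05 and n = 100 is roughly 12–22%
(the acceptance suite recomputes it); with a single data-driven start —
close to common practice of starting an optimiser from eyeballed values —
it drops to about 2%.  Small cline p-values near the 0.05 boundary should
therefore be read cautiously; the clines detected in practice have
p ≪ 0.001, where the point is moot.

## Association statistics

Residuals of each trait are correlated with SFR residuals.  The method is
gated per trait by Shapiro–Wilk at α = 0.05 (configurable): Pearson's r
when normality is not rejected, Spearman's ρ otherwise, with two-sided
t-approximation p-values (n − 2 df).  The six-trait family of p-values is
corrected by Benjamini–Hochberg; pairwise trait-residual correlations are
reported as a symmetric matrix (Spearman as soon as either member's
residuals deviate from normality).  Common-garden ecotype groups are
compared per life stage by the Kruskal–Wallis rank-sum test with mid-ranks
and tie correction — mandatory here, since the discrete ladder guarantees
heavy ties.  Note the chi-square approximation to the KW p is coarse for
heavily tied samples of a dozen observations (exact-enumeration error up to
~0.1 in mid-range p); at the group sizes used it is adequate.

## Synthetic studies

The generator emulates the field design: ~100 snails uniform in arc length
along a gently curved ~76 m path with 0.6 m Gaussian off-path jitter;
sigmoid trait clines whose directions mirror the field pattern (areas and
S2 rising towards the wave end, S1 falling; the foot-area cline centred at
the substrate transition ~30 m, the size cline shifted to ~50 m); a
160-quadrat fucoid survey with presence probability decaying logistically
past 50 m; two-round flume trials where per-flush survival is
logistic((true resistance − flush velocity)/scale), scale 0.1 m/s (0 gives
a hard threshold); ~10% non-attachers; 13% missing foot areas.  An optional
coupling adds β × (trait residual) to a snail's true resistance, creating a
causal trait→resistance link for power studies.  Common-garden groups draw
true resistances from per-ecotype Gaussians (juveniles 0.8/1.4 m/s,
adults 1.5/2.2 m/s, sds 0.5–0.6) and run one flume round.

What passing on synthetic data does *not* show: the generator draws traits
independently around their clines (no trait covariance beyond optional
couplings), uses Gaussian noise (no outliers or measurement error
structure), and places snails uniformly (no spatial clustering).  Real-data
behaviour under those violations is untested.

## Problem sizes

The acceptance suite uses 500 null replicates for LRT calibration and 100
shores for parameter recovery, both at n = 100 with 4 jittered restarts per
fit; recovery checks use median errors.  Width is the weakest-identified
cline parameter: with ecotype means two pooled SDs apart at n = 100 its
median relative error is roughly 35–60% depending on the replicate seeds
(centre and means are far tighter, ~2 m and ~0.06 respectively), so width
estimates at this signal strength should be read as order-of-magnitude.
Default pipeline fits use 20 restarts.
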