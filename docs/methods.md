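# Methods

## Geodesy

All distances and bearings are great-circle quantities on a sphere of
radius 6371.0088 km (haversine distance, standard initial-bearing formula).
Every distance in the analysis is under ~50 km; the ellipsoidal correction
at that scale (< 0.3%) is far below GPS noise, and the spherical model has
simple independent oracles (spherical law of cosines, planar small-area
limits) used throughout the tests.  Timestamps are parsed as UTC at seconds
resolution; duplicate timestamps within a bird are collapsed to the first
fix, as loggers occasionally repeat a record.

## Track cleaning and segmentation

Filters are applied in the order escape strip → speed filter → final-exit
segmentation, so the segmenter sees the cleaned track:

* **Escape strip.** The leading run of fixes within 500 m of the release
  point is removed; later re-entries into that circle are kept, because only
  the *initial* escape response is to be excluded.
* **Stop filter.** Fixes with logger speed < 5 km/h are dropped (the
  boundary value 5.0 is kept).  Stops removed this way still contribute to
  the virtual vanishing time, which is measured on the clock, not on the
  retained fixes.
* **Final-exit segmentation.** "Inside" an analysis radius means distance
  to the release point ≤ radius.  With L the last inside index, the segment
  is fixes[0 … L+1]; the exit fix L+1 (the first fix beyond the radius after
  the last inside fix) terminates the segment.  No interpolation is done at
  the crossing: at 1 Hz and cruise speed the crossing error is under ~25 m.
  A track whose last fix is still inside is flagged `never_exited`; segments
  with fewer than 3 fixes are `too_few_fixes`.  Both flags are per radius,
  so a bird can be analysable at 2 km but not at 5 km (logger death, slow
  birds hitting the simulation's duration cap — both occur in real data and
  in the generator).

The release point is taken from the site configuration, not from the first
fix, which may already be in flight.

## Following screen

The field procedure for spotting birds flying together is visual; the
package uses an explicit surrogate so the exclusion rule is reproducible:
fixes of one bird are matched to the nearest-timestamp fixes of another
(slack ≤ 2 s), and a contiguous run with separation ≤ d_max = 100 m lasting
≥ t_min = 120 s inside the 2 km segment window is a following event.  Both
thresholds are configuration keys and are recorded in the exclusion log.
Same-group dyads lose one member by a seeded uniform draw; cross-group
dyads lose both (the behaviour cannot be attributed to either treatment).
Exclusion flags are idempotent across events, and re-running with the same
seed reproduces the exclusion set exactly.

## Metrics

Step directions are home-relative: θᵢ = bearing(fixᵢ → fixᵢ₊₁) −
bearing(fixᵢ → home), wrapped to (−180°, 180°], with the bearing to home
recomputed at every step's start fix.  At ≤ 5 km from the release point and
~35 km from home the difference from using the fixed release-site bearing
is below 1°, but the per-fix definition is exact.  Zero-displacement steps
are skipped (their bearing is undefined), which also makes all four metrics
invariant to duplicated fixes.

Both efficiency indices share the segment path length as denominator and
are anchored at the segment's first fix (the first fix beyond the escape
radius):

* efficiency index = distance(first fix, exit fix) / path length;
* homing efficiency index = [distance(first fix, home) − distance(exit fix,
  home)] / path length.

The common anchor and denominator make "homing efficiency ≤ efficiency" an
exact triangle-inequality consequence and give a straight homeward flight a
homing efficiency of exactly 1.  Anchoring the homing numerator at the
release point instead (offered as `hei_anchor="release_point"`) breaks both
properties once the escape strip removes the first 500 m: on a straight
homeward track it yields ≈ (2000 m)/(1500 m) ≈ 1.35.  For real tracks the
two anchors differ by only a few percent, since the anchor sits within
~525 m of the release point while the numerator spans kilometres.

The virtual vanishing time runs from the first raw fix of the track (the
proxy for the release instant — loggers start recording at release) to the
exit fix, so loitering inside the radius counts even when the stopped fixes
themselves are filtered out.

## Directional statistics

Each bird is embedded as the Cartesian mean-vector point of its step
directions, (x, y) = (mean cos θ, mean sin θ): direction and concentration
in one bivariate observation.  Groups are compared with a two-sample
Hotelling T² (pooled unbiased covariance), p-values from
F = (n−3)/(2(n−2))·T² on (2, n−3) df; both T² and F are reported because
published "test statistic" values are easy to mis-read between the two
scales.  A unit-vector variant (direction only) is available as a
configuration switch.  Group summaries use the second-order mean vector,
the Cartesian average of individual mean vectors.

One property worth knowing: in this design treatment assignment is
stratified across release sites (nearly equal site composition in both
groups by construction).  A pooled two-sample T² ignores that
stratification, so when a real site effect exists the treatment comparison
is conservative — its null p-values pile up above uniform.  The test's
p-value uniformity is therefore verified under its own bivariate-normal
null; on pipeline null replicates the treatment Hotelling p is
right-shifted, which is expected behaviour, not an error.

## Linear models and effect sizes

Each metric is modelled as `metric ~ group + release site` by OLS with two
binary indicators (experimental = 1, site 2 = 1; positive differences mean
larger values in the experimental group / at site 2) and no interaction,
with Type II sums of squares (statsmodels).  Virtual vanishing times are
natural-log transformed before fitting and their mean differences reported
on the log scale.  Partial η² = SS_term/(SS_term + SS_resid), identical to
F/(F + df_den) at one numerator df.  Cohen's d is computed from the term's
t statistic as d = t·√(1/n₁+1/n₂) with the 95% CI from inverting the
noncentral-t pivot; the mean-difference CI is the ordinary coefficient t
interval.  95% is used wherever a confidence level is needed.  Residual
diagnostics report Shapiro–Wilk W/p and QQ pairs of standardized residuals
against Blom plotting positions.  A constant response is reported as F = 0
for both terms rather than 0/0.

## Power

For a target partial η², f² = η²/(1−η²), noncentrality λ = f²·N (total N),
denominator df N − 3 (intercept + two predictors); power is the
noncentral-F survival probability at the central critical value,
α = 0.05.  This is the conventional fixed-effects regression
parameterisation.  Note that power at a printed two-decimal effect size is
sensitive to the rounding of that input: near η² = 0.26, N = 31, a change
of 0.001 in η² moves power by ≈ 0.05 percentage points, so third-decimal
disagreements with tables computed from unrounded inputs are expected.

## Synthetic tracks

The generator is a biased correlated random walk at 1 Hz.  Each second the
heading is drawn from a von Mises distribution with concentration κ centred
on the circular mix of the previous heading (weight 1 − w) and the
perceived home direction (weight w); the perceived home direction is the
true bearing to the loft deflected by a site-specific offset.  Step length
is speed/3.6 m with speed ~ N(65, 8) km/h truncated ≥ 5.5; recorded
positions get isotropic N(0, 3 m) GPS noise; birds finish at 6 km from the
release point or after 30 minutes.

Default conditions (chosen once, as the study conditions the pipeline must
cope with):

| parameter | default | why |
|---|---|---|
| cells (rel1/exp1, rel1/exp2, rel2/exp1, rel2/exp2) | 12, 12, 12, 13 | the design's published cell counts |
| site geometry | home bearings 261°/336°, distances 34.2/39.3 km | the two release sites' printed home geometry; coordinates are derived from the loft by fixed-point inversion |
| κ | 4 | tortuous enough that orientation weight w has leverage on efficiency at 2 km |
| w (bias weight) | 0.35 | produces efficiency/mean-vector-length ranges of ~0.4–0.9 typical of initial homing segments |
| per-bird w jitter | SD 0.05 | persistent individual quality differences; keeps between-bird variance from averaging out over longer segments |
| site bias | site 1: −15°; site 2: −30° and w − 0.12 | anticlockwise deflection at both sites, weaker and more deflected orientation at site 2; yields a mean site η²p ≈ 0.26–0.28 across the eight models with site 1 > site 2 on every metric |
| treatment effect | 0 | the design's null: passive exposure leaves orientation unchanged |
| stops | 0.3 episodes/min, geometric mean 20 s, speeds 0.3–4.5 km/h | produces the sub-5 km/h fixes the stop filter must remove |
| escape phase | 60 s with w = 0 | undirected circling after release |
| follower dyads | 8 | exercises the following screen; with the one-or-both exclusion rule, 49 birds → ~34–40 analysed |
| releases | alternating treatments, 6 min apart, two sites on different days | matches the release protocol; gives follower dyads temporal overlap and independent birds very little |

What the generator does *not* emulate: wind drift, terrain and landscape
guidance, route loops/soaring, logger dropouts, heteroscedastic GPS error.
Passing tests therefore show that the statistical machinery is correct and
calibrated for data with this covariance structure, not that the biological
effect sizes of any particular field study are recovered.

## Calibration experiments

* **Null calibration.** 2000 simulate→analyse replicates at
  treatment_effect = 0 (all other defaults unchanged): the efficiency-index
  treatment term rejects at 5.3% ± 0.5% and its p-values are uniform; the
  release-site fitted difference for efficiency is negative in ~100% of
  replicates (site 1 more efficient).
* **Power closure.** The treatment effect is an increment δw to w; a
  common-random-numbers pilot measures the metric-scale response Δ(δw) and
  the within-cell SD σ, and δw is chosen so that Δ = 2σ√(f²) — the balanced
  two-group difference corresponding to the target partial η².  At target
  η² = 0.26 with 31 birds (cells 8/8/8/7, no followers) the empirical
  detection rate over 300 replicates falls within the Monte-Carlo margin of
  the analytic 89.0%.

Replicate experiments run the single-radius (2 km) configuration of the
pipeline; this halves their cost and the 2 km models are the primary
endpoint.  Problem sizes (2000/300/500 replicates, 400-bird pilots) were
chosen to put Monte-Carlo standard errors well inside the asserted bands.

## Numerical notes

* "Inside the radius" is `distance ≤ radius`; geometric fixtures avoid
  placing fixes exactly on the boundary.
* The efficiency indices are clamped to their mathematical ranges to guard
  float overshoot (e.g. 1 + 2⁻⁵² on perfectly straight tracks).
* The noncentral-t CI inversion brackets the noncentrality adaptively
  outward from t, because `nct.cdf` underflows to NaN far from its centre.
* Tie-break in same-group following exclusions: events are processed in
  sorted (bird_a, bird_b, start) order with one uniform draw each, so a
  fixed seed reproduces the exclusion set bit-for-bit.

## Known limitations

* The following screen is a proximity heuristic standing in for expert
  visual inspection; its thresholds are honest configuration, not estimates.
* Hotelling's treatment comparison is conservative under release-site
  heterogeneity (see above); a stratified or permutation variant would be
  the remedy but is out of scope.
* GPX ingest covers GPX 1.1 track points with `<time>` and an optional
  `speed` extension — not the full GPX feature surface.
* The real study's numerical results (its specific F, T², p values) depend
  on its deposited tracks and are not reproduced here; only the qualitative
  release-site pattern is checked on synthetic data.
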