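# Methods

## Coordinate conventions and units

Screen coordinates are pixels with the origin at the monitor centre,
x rightward, y upward; field coordinates are degrees of visual angle
relative to the fixation object, same axes. Visual angle is computed per
axis as `arctan(physical offset / viewing distance)` — the convention
under which 300 px on the default 40 cm / 1280 px screen at 57 cm
subtend 9.34°. The alternative `2·arctan(half-extent/d)` convention is
deliberately not used; the two differ only in the third decimal at the
eccentricities involved, but the single-arctan form is what the default
fixation geometry is quoted in. Pixels must be square within 1 %
(anisotropic conversion is not supported; the canonical apparatus is
square-pixel). Staircase increments are kept in **pixels** (the unit the
staircase rules are specified in) and converted to degrees through the
screen model at presentation time.

## The simulated observer

The observer model replaces the human participant and the eye tracker.
Its assumptions, and what they do and do not capture:

* **Geometry.** The scotoma is a fixed, axis-aligned, upright ellipse.
  Real blind spots are only approximately elliptical and symmetric;
  consequently passing recovery tests show that the *procedures* are
  unbiased and precise for the model class they assume, not that the
  ellipse assumption holds for a given human.
* **Psychometrics.** A point's see-probability is
  `guess + (1 − guess − lapse) · σ(d / s)` with `d` the signed distance
  to the ellipse boundary (negative inside) and `s` the boundary
  softness in degrees; `s = 0` degenerates to a step function with 0.5
  on the boundary. The signed distance uses the along-ray scale
  `(r − 1) · w·h / (2·√((h·cosθ)² + (w·sinθ)²))`, which is exact on the
  axes and cheap, smooth and monotone elsewhere — only the zero set and
  monotonicity matter to the psychometrics.
* **Extended targets** (heat-map cells, scaling ellipses) are "seen if
  any part is seen": the maximum point visibility over a deterministic
  sample of 64 outline and 25 interior points. Rectangle sampling
  includes the four corners exactly; since the elliptical radius is
  convex, a cell is entirely inside the ellipse iff its corners are, so
  for a sharp observer the sampled rule is *exact*, not approximate.
* **Noise.** One isotropic Gaussian gaze offset per trial
  (`fixation_jitter_sd`, default 0.3°; trials last only ~400 ms, so no
  within-trial drift is modelled), plus an independent Gaussian click
  error along the movement direction for moving-probe reports
  (`click_error_sd`, default 0.2°, with an optional directional bias for
  late clicks, default 0). Guess and lapse rates default to 0.02. These
  response-noise values are modelling choices pitched at a practised
  observer — no published human response model exists for this task —
  and sit roughly where they reproduce study-like block-to-block
  precision (location Stdist of a few tenths of a degree).
* **Defaults.** Centre (16.00, −2.05), size 6.28° × 7.02°, matching the
  average healthy right-eye blind spot, so simulated output is
  comparable with published group data at a glance.

## Border-point detection

Paths are planned sequentially (horizontal through the prior region's
vertical centre; vertical through the midpoint of the first pair;
horizontal through the midpoint of the vertical pair). The prior search
region defaults to [12°, 20°] × [−6°, 2°]: the interactive tool lets the
user steer the probe by hand, which has no meaning in simulation, so a
fixed canonical rectangle stands in. A path that misses the scotoma
raises rather than re-centring silently; the caller can widen the prior.

Simulated clicks sit at the true crossings of the path with the
gaze-shifted ellipse plus click error, two per pass (disappear/reappear),
with three round trips per path by default. Clicks are clustered by
sorting along the path's free axis and splitting at the largest gap —
deterministic, and exact for well-separated borders; the split is
rejected as degenerate when a cluster would hold fewer than two clicks
or the cluster means are closer than 0.5° (no real blind spot is that
narrow; a smaller separation means the pass failed).

Medium mode's four extra paths sit at x = cx ± w/4 and y = cy ± h/4
using the Low-stage estimates — a symmetric, configurable choice (the
protocol fixes only the *number* of extra paths, not their exact
placement). High mode (± w/8, h/8 additionally) is wired through but
flagged experimental and untested against any reference data.

## Staircase

The state machine follows the transformed up-down rules: 1-up-1-down
until the first reversal, then 1-up / 3-consecutive-down; every reversal
advances the step schedule (30, 15, 7, 3 px, largest first — the
schedule is applied in operational order), and the reversal-causing move
already uses the new step, the convention of standard transformed
up-down implementations (it affects only transients). "Three negative
answers" is read as three *consecutive* noes with the counter reset by
any yes — the 79 % convergence target holds only under the consecutive
rule. Termination is exactly 20 successful trials regardless of reversal
count, with the threshold at the final trial's increment; a
`require_reversals` flag optionally extends the run until the fourth
reversal. Negative increments (outside the raw border point) are
permitted without bound. Trials with gaze outside the fixation tolerance
(1.5° default, boundary inclusive) are logged, discarded and re-run with
fresh randomness, up to a generous attempt cap.

`convergence_probability` verifies the convergence level by simulation:
long (≥200-trial) staircases against a caller-supplied monotone
psychometric, converged level taken as the mean presented increment over
the final half of each run, averaged across runs. With a logistic
psychometric of scale 15 px and the default rules this lands at
P(no) ≈ 0.80, within the Monte-Carlo band of the 0.5^(1/3) ≈ 0.794
theory; the residual ~0.01 excess reflects the mild asymmetry of the
1-up-3-down walk around its equilibrium, which the mean-level summary
does not remove.

## Validation

The heat-map rectangle is built from the **staircase-adjusted** size
estimates — the section runs after the staircase in a full block, so
those are the freshest numbers (the raw stage can be substituted by
calling `build_heatmap_grid` directly). For a sharp noise-free observer
the sub-threshold region is exactly the set of cells entirely inside the
ellipse; the outer-edge size estimate therefore under-covers by the
partial cells at the rim. In degrees this error vanishes with
resolution, but in *cell units* it oscillates with how grid lines align
with the ellipse apices (the 1.2 height margin parks the apex at 5/6 of
the half-rect, so some resolutions lose 1⅓ cells); two cells per
dimension is the honest bound, one cell is not. Human-like observers
with jitter and soft boundaries produce intermediate proportions in rim
cells, which the 0.5 threshold splits roughly at half coverage, so the
practical bias is smaller. Connectivity of the sub-threshold set is not
enforced (real maps can contain isolated low-visibility cells).

The scaling section keeps the estimated aspect ratio and tests 10
coefficients evenly spaced over [0.6, 1.2], 10 trials each. The
visibility-vs-size curve is fitted with the logistic
`f(x) = 100 % / (1 + exp(−t(x − x₀)))` by unweighted least squares on
the percentage scale (no fitting method is canonical for these 10-point
curves), multi-started over candidate inflection points with t > 0
enforced; all-equal data are rejected as unfittable. `zero_visible_size`
reports the largest tested coefficient at and below which nothing was
ever seen — a per-observer conservative invisibility size.

## Statistics and aggregation

Sample (n−1) standard deviations throughout. Per-observer aggregation:
arithmetic means, SDs and min–max ranges of block estimates, the
standard distance of block locations, and the summed standard distance
of the four cardinal border points (per stage). Across observers, SD and
Stdist columns are RMS-aggregated (square root of mean variances /
squared Stdists) while plain columns are arithmetically averaged; the
safe zone is `0.5 · (min width, min height)` over per-observer means,
reported rounded half-away-from-zero to 2 decimals (internal computation
at full precision). On the bundled 12-observer reference table this rule
yields a 2.70° × 2.90° safe zone. The t comparisons are classical:
paired t (df = n−1) for raw vs adjusted summed Stdist, pooled-variance
two-sample t (df = n₁+n₂−2) for width-SD vs height-SD; p-values are
logged but never used as pass/fail criteria.

## Parameter recovery: which estimates count

Recovery of the ground-truth ellipse is evaluated on the
**detection-stage (raw)** width/height, which target the 50 % boundary —
i.e. the physical ellipse. The staircase deliberately re-targets points
to the 21 %-visible level, so adjusted sizes are a *biased* estimator of
the axis lengths by construction (~0.3° per point inward under the
default observer, more with heavier jitter); judging recovery on them
would conflate intended re-targeting with estimation error. Location is
always a detection-stage quantity.

## Problem sizes and determinism

Every stochastic routine takes a `numpy.random.Generator`; identical
(protocol, observer, seed) triples reproduce blocks bit for bit. The
convergence study uses 2000 runs × 200 trials; the block-level recovery
study uses 100 seeded Low-mode blocks — sizes at which the Monte-Carlo
error is comfortably inside the tolerances being checked while a full
run of everything stays in the tens of seconds on one core.

## Known limitations

* No rendering, audio, timing or hardware layer: stimulus presentation
  is a pure function call, and the response-backend seam (present
  stimulus → seen?, gaze) is where an eye tracker/display backend would
  attach.
* The observer has no filling-in phenomenology, no light sensitivity
  inside the scotoma, no learning or fatigue, and stationary parameters
  across a block.
* High mode's path geometry is an extrapolation and has no reference
  data behind it.
* The sigmoid fit treats proportions as homoscedastic; a binomial GLM
  would weight the tails differently (the plotted error bars are
  binomial standard errors).
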