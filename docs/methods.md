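# Methods

## The measurement model

Continuous-report spatial memory is summarized per trial by the Euclidean
distance between a placed location and an anchor. Two anchors matter:

* **studied** — the location trained to criterion (veridical memory);
* **remembered** — the participant's placement on the immediate test, a
  proxy for the internal representation that later cueing can act on.

*Memory stability* is the distance between a delayed placement and the
immediate placement; the *cueing benefit* of a cued association is the
participant's mean uncued stability error minus that association's own
stability error (positive = cueing helped).

Placements are modeled as a two-component mixture: with probability `p` an
isotropic bivariate Gaussian around the anchor with standard deviation `σ`
(memory success and precision), otherwise uniform over the screen with
density `1/(width·height)` per px² (guessing). The likelihood is maximized
under box constraints `p ∈ [0, 1]`, `σ ∈ [1, 800]` px. Trial-level success
labels compare the **unweighted** component densities (Gaussian density at
the placement vs. the uniform density), equivalent to a radial cutoff
`r* = σ√(−2 ln(2π σ² g))`; a flag switches to mixing-weighted posteriors.
The unweighted rule is the default because it matches the procedure the
analysis replicates; at `p` near 1 the two rules coincide for practical
purposes.

### Numerical choices

* Per-trial likelihoods are floored at 1e-300 before the log so a `p = 1`
  fit cannot produce `−inf` from a far-tail placement.
* Optimization: L-BFGS-B from five fixed starts spanning the box
  (p ∈ {0.5, 0.9, 0.99} × σ ∈ {30, 80, 200} px corners); the best NLL is
  kept and the fit is marked converged if any start converged. The NLL
  surface is smooth and two-dimensional; the test suite verifies the
  optimum beats an exhaustive 101×101 grid on every tested instance.
* Group-level fits pool cued and uncued trials across participants (eight
  trials per condition per participant are too few for stable individual
  per-condition fits); per-participant fits (for the studied-vs-remembered
  precision comparison) use all delayed trials from both rounds.

## Cue assignment

Before cueing, associations with immediate error above mean + 2 sample SDs
(n−1 denominator, strict inequality) are flagged and excluded from the
cued/uncued comparison; if fewer than two exceed the threshold the flagged
set is filled uniformly at random (seeded), if more, the largest errors are
kept. The remaining 16 associations are split 8-vs-8 by exhaustive
enumeration of all C(16,8)/2 = 6,435 unordered partitions, minimizing
|mean(cued) − mean(uncued)| immediate error; ties break to the
lexicographically smallest half. Because the halves are matched, the
*label* (which half is cued) is a seeded coin flip by default
(`deterministic_labels=True` disables it). A random-restart heuristic is
provided for designs too large to enumerate.

## Robust regression and permutation inference

The vigilance-benefit and learning-benefit relationships use iteratively
reweighted least squares with Tukey bisquare weights:
`u = r / (c·s·√(1−h))` with `c = 4.685`, `s = median(|r|)/0.6745`, `h` the
OLS leverage; `w = (1−u²)²` for `|u| < 1`, else 0; iterate until the
coefficient change falls below 1e-8 (max 100 iterations). This is the
common default configuration of bisquare robust fitting; bit-level
compatibility with any particular implementation is a non-goal, but the
tests cross-check against an independent implementation (statsmodels RLM)
on heavy-tailed data. The slope SE and t come from the final weighted
least-squares fit with df = n − 2; the reported `r` is the plain Pearson
correlation of the raw data (a weighted variant is available).

The permutation test permutes the response vector uniformly, recomputes the
IRLS slope, and reports the two-sided add-one p-value
`(1 + #{|b*| ≥ |b|}) / (1 + n_perm)`, which is reproducible from its seed
and never exactly zero. Outlier-excluded OLS drops points with |z| > k SDs
in either variable before ordinary least squares; the default is k = 3,
with k = 2 available (both conventions circulate for this analysis).

One caveat established empirically: item-level rows are clustered within
participants (items share the participant's uncued-mean term and RT
reference), and the all-items permutation scheme ignores that. Over 1,500
simulated null studies the realized type-I rate at α = 0.05 was ≈ 0.06 —
mildly anti-conservative, within two points of nominal. A mixed-effects
item analysis would address this but is out of scope; the original design
pools items the same way.

## Group inference

Repeated-measures ANOVAs use the standard fully-within univariate
decomposition (each effect tested against its interaction with subjects);
partial η² = F·df_num/(F·df_num + df_den). No sphericity correction is
applied by default — the only factor with more than two levels is the
rating-distribution factor — and two-level effects satisfy F = t² against
the paired t-test exactly. Cohen's d is mean difference / SD of differences
for paired contrasts and pooled-SD for independent ones. Constant-input
designs return a flagged degenerate result rather than an exception. No
multiple-comparison correction is applied across analyses; the pipeline
reports each test as-is, mirroring common practice in this literature, and
this is a known limitation.

Cue discrimination uses, per participant, the 2×2 Pearson χ² (df = 1, no
continuity correction) of cue status against "high-confident cued" vs. any
other rating; a zero margin yields χ² = 0 by convention, and expected cell
counts below 5 trigger a logged warning rather than an exact test (the
design has only 16 classified associations per participant). Participants
with p < 0.1 — a trend criterion, deliberately liberal so that even weak
explicit knowledge counts — are labeled discriminators. The learning
factor is the first principal component of the z-scored (mean immediate
error, mean training rounds) pair, sign-aligned so higher = worse learning.

## The synthetic-data generator

### What it emulates

Per participant *i*, an ability latent `λᵢ ~ N(0,1)` scales the immediate
placement noise log-linearly (`σᵢ = σ_imm · exp(0.3 λᵢ)`) and the Poisson
mean of training rounds beyond the two-round minimum
(`rounds = 2 + Pois(0.55 · exp(0.4 λᵢ))`), so slow learners are also
imprecise. Placements follow the same guessing+Gaussian mixture the
analysis fits. Delayed round-1 placements are anchored on the **immediate**
placement; round-2 placements on round-1 (drift SD 30 px). This anchoring
is what produces the remembered-better-than-studied structure downstream.
Off-grid Gaussian draws are redrawn rather than truncated or clipped
(truncation would bias parameter recovery); a config flag disables
redrawing.

Cue assignment inside the generator runs the real assignment procedure on
the simulated immediate errors. The cover-task session is built to the
design's balance constraints: 96 trials, ITI durations 10/12/14/16 s (one
2-s arrow per 2 s), 24 cue events — one per cued object per third of the
session, two per ITI duration per third, half on word and half on
pseudo-word trials. Arrow RTs are participant baseline + an ITI-level
vigilance draw `vⱼ ~ N(0, 60 ms)` + arrow-level jitter (floored at a
physiological 150 ms); lexical RTs add a fixed offset and are inflated by
32 ms after a cue. For each cued object, the delayed noise SD is reduced by
`max(0, 6 + 3 λᵢ + 0.2 v̄ⱼ)` px (floored at 5 px), where `v̄ⱼ` is the mean
vigilance draw over that object's three re-exposure ITIs — the same latent
that slows the arrows, so slower pre-cue responding genuinely causes larger
benefits. Discrimination ratings come from an equal-variance
signal-detection model with per-participant `d' ~ N(1.0, 0.8)` and three
criteria at `d'/2 + {−0.8, 0, +0.8}`.

### Parameter defaults, units, and rationale

| parameter | default | why |
|---|---|---|
| participants / objects / cued / uncued / flagged | 23 / 18 / 8 / 8 / 2 | the study design |
| grid, px/cm | 1280×1024, 38.697 | display; scale reconstructed from the printed 264.3 px ≡ 6.83 cm pair (the 77.3 px ≡ 2.00 cm pair gives 38.65 — consistent to rounding) |
| σ_immediate_base, guess_imm | 55 px, 0.02 | yields ≈ 77 px mean immediate error |
| rounds_mean_base | 0.55 | yields ≈ 2.55 training rounds per association |
| σ_delay_uncued, guess_delay | 42 px, 0.05 | ≈ 1.1 cm fitted precision; ≈ 93–95 % memory success |
| cueing_benefit_base / ability coupling | 6 px / 3 px per SD | small stability benefit, larger for worse learners |
| vigilance coupling | 0.2 px/ms | slower pre-cue RT → larger benefit |
| RT scale | 550 ± 80 ms baseline, 60 ms ITI, 40 ms jitter | plausible speeded-response values |
| post-cue inflation | 32 ms | the reported post-re-exposure slowing |
| d′ mean ± sd | 1.0 ± 0.8 | group-level discrimination with a sizable non-discriminator fraction |

Studied-location sampling (margin 125 px, minimum separation 100 px) is an
explicit guess — the original layout rules are not documented — and both
knobs are exposed without any fidelity claim.

Seeding: one master seed; per-participant substreams are spawned
deterministically (adding participants never perturbs earlier ones), and
identical configs produce bit-identical datasets.

### What the generator does *not* emulate — and what passing tests show

The generator is conjugate to the analysis models by construction: noise
really is isotropic Gaussian + uniform, the vigilance-benefit link really
is linear. Passing recovery tests therefore show the estimators are
correct and calibrated *under the assumed model*, not that real data obey
it. Known departures of real data: anisotropic and edge-biased placement
errors, swap/misbinding errors toward other objects' locations, non-
stationary vigilance (time-on-task drifts), lexical content effects, and
retrieval practice effects of the immediate test. Also, because a delayed
round-1 guess anchors round 2 near it, guessed associations produce large
correlated stability errors in both rounds; this makes the per-study
cueing contrast noisier than in the original report, so a single simulated
23-participant study frequently fails to reach significance on the cueing
ANOVA even though the population effect is positive (the structural tests
therefore average over ≥ 100 simulated participants).

## Problem sizes in the validation suite

Parameter recovery runs 20 replicates at n = 2000 trials; grid-oracle
checks use 10 instances of 200 trials against a 101×101 grid; permutation
calibration uses 500 simulated 23-participant null studies at 200
permutations each; structural emulation uses 150 simulated participants.
These sizes give Monte-Carlo error comfortably inside each test's
tolerance while keeping the full suite around five minutes.
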