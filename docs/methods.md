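# Methods

## The measurement problem

Remote audiences watch streamed content at home through a browser. A
webcam face tracker returns 68 facial landmarks per frame, from which we
want a scalable, non-invasive index of cognitive engagement. The working
hypothesis is the *stillness hypothesis*: in a seated viewer, engagement —
and especially immersion — narrows attention and suppresses fidgeting, so
less head movement indicates more engagement.

`stillwatch` implements the full measurement chain: a head-movement metric
in physical units, validity checks based on inter-subject correlation
(ISC), probe-caught experience-sampling aggregation, and the statistical
battery that tests the stillness hypothesis against momentary,
retrospective and behavioural engagement outcomes.

## Head-movement metric

Raw tracker output is downsampled to 1 Hz by keeping, for every second
`s`, the earliest frame with timestamp in the half-open bin `[s, s+1)`.
Seconds without a frame stay empty; nothing is interpolated. For each
retained frame, the centre of each eye is the mean of its six landmarks
(numbers 37–42 and 43–48, 1-based, in the iBUG-68 layout) and the
interocular distance (IOD) is the Euclidean distance between the two
centres, in pixels. Head movement at second `t` is the planar displacement
of the nose tip (landmark 31) since the previous retained second,
converted to centimetres with the average adult IOD:

    movement(t) = ‖nose(t) − nose(t−1)‖ · 6.3 cm / IOD(t)  [cm/s]

Conventions, all configurable:

- the first sample's movement is defined as 0 (no preceding frame);
- a step across a gap longer than 1 s is *missing*, never displacement
  divided by elapsed time — spreading a displacement over unobserved
  seconds would fabricate data;
- the IOD used for a step is the later frame's (`iod_policy="later"`);
  the mean of the two frames is available and differs only at second
  order;
- samples strictly above 20 cm/s are excluded as outliers, once, before
  any aggregation;
- frames with coincident eye centres (zero IOD) are flagged degenerate
  and treated as missing.

Because the pixel→cm conversion uses the same frame geometry that
produced the displacement, the metric is invariant to uniform rescaling
of pixel coordinates; a property test asserts this to 1e−9 relative.

Aggregation over any window is the arithmetic mean of the present samples
in it (half-open second intervals). Minute profiles are consecutive 60 s
bins; a 30 s bin width is available where a finer pairing is wanted.

## Experience sampling

23 audio probes, roughly a minute apart, prompt a categorical report of
momentary state: **distracted**, **engaged**, **reflecting**, or
**immersed** (task-unrelated thought, plain attentiveness, task-related
thought, deep involvement). Participants with fewer than 10 responses are
excluded, as are participants with fewer than 600 retained tracking
samples.

The *pre-probe mean* is the movement average in the interval from just
after the previous probe's onset second up to (but excluding) the current
probe's onset second; for the first probe the interval starts at 0. The
onset second itself belongs to the *post*-window because the keypress
response produces a movement spike — including it in the pre-window would
bias against stillness. Probes are ~1 min apart, so these inter-probe
windows form a natural non-overlapping partition; a fixed 30 s pre-window
is available for sensitivity analysis.

Per-probe aggregation averages, for each probe and response category, the
pre-probe means of the participants who gave that category at that probe.
Cells backed by fewer than 3 participants are excluded (their means would
be outlier-dominated).

## Inter-subject correlation

ISC validates that the momentary measures carry stimulus-locked signal:
if the content drives behaviour, participants' time series should agree
beyond chance. For every unordered pair of participants the movement
series are correlated (product-moment by default, rank-based optionally)
over the seconds both have present, and the distribution of pair
coefficients is tested against zero with a one-sample t-test
(df = n_pairs − 1; two-sided by default, with a directional option).

Details that matter:

- pairs with fewer than 100 overlapping seconds, or zero variance in
  either series, are dropped and counted — not recorded as r = 0;
- each series' *first* sample is excluded from the correlation: its value
  is 0 by definition, a deterministic artifact shared by every
  participant. Leaving it in measurably biases the null upward (the
  calibration test catches this);
- for the categorical measure, one category at a time is dummy-coded
  (target response → 1, any other response → 0, missing stays missing)
  and pairs are correlated with Spearman's coefficient over commonly
  answered probes. On binary indicators this is monotone-equivalent to
  the phi coefficient, which the tests exploit as an oracle;
- movement ISC is reported for the control condition only by default:
  fixed-time probes in the sampling condition would add coordinated
  keypress movement and inflate ISC. A flag overrides.

A robustness variant excludes participants in the lowest quartile of mean
and/or SD of movement (very still participants contribute near-constant
series); "lowest quartile" is strictly below the 25th percentile, and the
union of the two flags is excluded by default.

The one-sample t-test across pairs is the field's standard but not exact:
pair coefficients that share a participant are not independent, which
widens the t distribution slightly in heavy-tailed data. The calibration
test bounds the realised type-I rate under the generator's null.

## Stillness-hypothesis battery

- **Momentary:** for each of the six category pairs, per-probe means are
  compared with a paired test across probes, pairing by probe and
  dropping probes that lack either cell. A Shapiro–Wilk gate at α = 0.05
  on the paired differences selects the Wilcoxon signed-rank test (the
  usual outcome for right-skewed movement) or the paired t-test; p-values
  are Bonferroni-corrected over the family of six. Zero differences are
  dropped (signed-rank convention); scipy's exact distribution is used
  for small samples without ties, the normal approximation otherwise.
  Contrasts with fewer than 3 usable probes are reported as
  not-computable, never silently dropped.
- **Retrospective:** Spearman correlations between each participant's
  overall mean movement and (a) narrative engagement (questionnaire mean,
  1–5) and (b) enjoyment (0–100), reported uncorrected, mirroring the
  reporting structure of the momentary family.
- **Behavioural intention:** participants are split by whether they
  wanted to continue watching; each group's per-minute mean profile
  (equal-weighted over members' minute means) is compared minute-by-minute
  through the same gated paired test. Bin width defaults to 60 s and is
  configurable (30 s roughly doubles the paired bins on a 30-minute
  piece).
- **Experimental manipulation:** narrative engagement is compared between
  the control and experience-sampling conditions with a Welch
  (unequal-variance) t-test, alongside the per-condition proportion of
  positive behavioural intention.
- **Quadrant groups:** participants are median-split on engagement ×
  enjoyment (pooled medians; "high" is strictly above the median, ties go
  low). Groups smaller than 6 are flagged not analysable, and analysable
  groups are compared pairwise on their minute profiles. This analysis
  explains a movement–enjoyment null: a discordant low-engagement /
  high-enjoyment group with elevated movement attenuates that
  correlation while leaving movement–engagement intact.

All tests are pure functions of their inputs; reports log every gate
decision, exclusion and family size.

## Synthetic cohort generator

The generator produces complete cohorts — landmark streams, probe
responses, retrospective scores — with ground truth, so every pipeline
stage is testable without any recorded data.

**States.** Each participant follows a sticky first-order Markov chain at
1 Hz over the four engagement states with transition matrix
`p·I + (1−p)·1⊗π` (persistence `p = 0.95`, ~20 s dwell), whose stationary
distribution is exactly the configured marginals
π = (.10, .41, .245, .245). *Shared events* — cohort-level random onset
seconds (about one per 90 s on average, 3 s long) — force each participant
into the distracted state with hazard 0.25 per event second. This is the
stimulus-locked component: coupling arises through behaviour, not through
added common noise, and its sticky aftermath (~20 s of elevated
distraction after each event) is what the movement ISC detects. Realised
distracted occupancy lands near .17 with the events included.

**Movement.** Per-second movement is lognormal with shared shape σ = 1
(skewness ≈ 6) and state-dependent mean (1.15, 0.50, 0.52, 0.29) cm/s —
distracted ≫ reflecting ≈ engaged > immersed — multiplied by a
per-participant lognormal fidgetiness trait (σ = 0.35, unit mean). In the
experience-sampling condition a keypress spike (2 cm/s for 3 s) is added
from each probe onset to the *observed* movement only.

**Landmarks.** A rigid 68-point face template realises the participant's
pixel IOD (mean 63 px, SD 8 px across participants); the head performs a
random-direction walk displaced by `movement · IOD / 6.3` pixels each
second. The rendering is the metric's inverse by construction: with zero
coordinate jitter, re-measuring a rendered stream recovers the true
movement to numerical precision (tested at 1e−6 cm). Optional
within-second extra frames exercise the 1 Hz downsampler; optional
Gaussian coordinate jitter adds tracker noise.

**Responses.** The response at each probe is the true state at probe
onset, flipped to a uniformly random *other* category with probability
0.1 and dropped with probability 0.1.

**Retrospective scores.** Narrative engagement is a negative linear link
on the participant's spike-free mean movement,
`clip(4.2 − 1.2·m + N(0, 0.5), 1, 5)`; enjoyment follows engagement
(`25·(eng − 1) + N(0, 8)` on the 0–100 scale); intention is a logistic
draw on engagement (centre 3.0, slope 2.0). A *discordant* fraction
(default 25%) receives a 1.8× movement inflation and a +25 enjoyment
offset on top of the shared link: those participants end up
low-engagement / high-enjoyment / high-movement, attenuating the
movement–enjoyment correlation while the cohort's engagement–enjoyment
correlation stays high (~0.7). The keypress spike is deliberately kept
out of the retrospective link — it is an artifact of responding, not
fidgeting — so the default configuration carries a genuinely null
condition effect.

Default parameters were set in one calibration pass so that a default
cohort's descriptives land near the study conditions the package targets
(pooled mean ≈ 0.67–0.7 cm/s, skewness > 2, response marginals ≈
17/36/23/24%, engagement ≈ 3.3, enjoyment ≈ 62–64, intention ≈ 63–66%)
and then frozen.

Everything is driven by a single master seed through spawned
`numpy.random.SeedSequence` streams, so cohorts are reproducible
participant-by-participant and written files are byte-identical across
runs.

### What the generator does and does not emulate

It carries the statistical structure the analyses assume: right-skewed
movement, state-dependent stillness, stimulus-locked coupling, post-probe
spikes, negative movement–engagement links, the discordant subgroup, and
a null experimental manipulation. It does **not** model facial
deformation, 3-D head pose, tracker dropout patterns, response latency,
or individual differences beyond a scalar fidgetiness trait. Passing
tests therefore demonstrate that the pipeline recovers these structures
when present — not that recorded webcam data satisfies them.

## Problem sizes and numerical choices

Statistical checks run on scaled-down cohorts chosen for adequate power
at desk-scale runtimes: ISC null calibration at 20 participants × 600 s
(200 replicates), ISC sensitivity at 30 × 1200 s (100 replicates),
stillness recovery at 64 sampling-condition participants × 1500 s (100
replicates, 23 probes), subgroup attenuation at 60 × 300 s, and
condition-effect calibration at 60 × 300 s (200 replicates). The
acceptance script reports a single full-scale cohort (132 × 1800 s).

Tie and degeneracy handling: constant inputs route to the nonparametric
path with a logged warning; all-zero paired differences are reported as
an exact no-effect result (p = 1) rather than an error; zero-variance
correlation inputs raise a degeneracy error rather than returning NaN.
Medians are computed over the pooled cohort, and quartile flags use
strict inequality against `numpy`'s linear-interpolation quantile.

## Known limitations

- The pairwise-ISC t-test inherits the mild anticonservatism of dependent
  pairs; calibration is verified empirically under the generator's null
  rather than guaranteed analytically.
- The head-movement metric is planar; depth motion and rotation project
  onto the image plane and are partially absorbed into the IOD rescaling.
- The inter-probe pre-window mixes states when the participant's state
  changed within the window, diluting (never inflating) momentary
  contrasts.
- The generator's enjoyment link is linear with additive noise; it does
  not reproduce ceiling effects or the full bimodality real enjoyment
  scales can show.
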