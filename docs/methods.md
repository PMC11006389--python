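# Methods

`divesat` analyses blood-oxygen bio-logger recordings from diving birds:
1 Hz time–depth records paired with sparse (5 or 15 s) intravascular P_O2
logs from either an arterial or a venous electrode.  This note documents
the models, the operational definitions behind each pipeline stage, the
synthetic-data generator, and the numerical choices, so a reader can judge
what a passing test suite does and does not demonstrate.

## Dissociation curve and O2 content

P_O2 is converted to hemoglobin saturation with a Hill curve,

    S(P) = 100 · Pⁿ / (P50ⁿ + Pⁿ),

with configurable `p50_mmHg` and `hill_n`.  The shipped defaults
(P50 = 36 mmHg, n = 2.9, reference pH 7.5) are placeholders standing in
for a measured emperor-penguin curve at resting pH and should be
recalibrated before analysing real electrode data.  No packaged result
depends on them: synthetic P_O2 is produced through the exact analytic
inverse of the same curve (forward ∘ inverse cancels to < 1e-9 pp), and
the content arithmetic uses saturations only.  No Bohr or temperature
correction is applied — intra-dive pH is unknown in this setting, and the
curve parameters are the single hook for alternative assumptions.

Hb-bound O2 content is `C = (S/100) · [Hb] · capacity` with defaults
18 g dl⁻¹ and 1.34 ml O2 g⁻¹ (24.12 ml O2 dl⁻¹ at full saturation).
Dissolved O2 is excluded throughout.  The arterio-venous difference is the
content difference; negative values (arterialized venous blood) are
reported, never clipped.

## Dive segmentation

A dive is a maximal interval with depth > 2 m lasting **strictly** more
than 2 min.  The source recordings never state an operational start/end
depth; 2 m is standard time–depth-recorder practice and is configurable.

Phases are rate-based: the raw depth gradient is averaged over a centered
5-sample window (shrinking at the edges so boundary rates stay one-sided),
descent is the initial contiguous span with downward rate ≥ 0.2 m s⁻¹,
ascent the final contiguous span of sustained upward rate, bottom the
remainder; the three phases tile the dive exactly.  A rate rule rather
than a %-of-max-depth rule is used because these shallow sub-ice dives
contain mid-dive excursions toward the surface.  "At maximum depth" means
depth ≥ 0.9 × maximum.  Vertical direction changes are dead-banded
(±0.1 m s⁻¹) sign flips of the smoothed rate.

## Per-dive saturation metrics

Blood-gas samples rarely coincide with dive boundaries, so start- and
end-of-dive saturations are the samples *nearest* the boundaries (a sample
up to half an interval outside the dive can be selected).  The peak is the
maximum over the dive, earliest sample on ties; the mean is the unweighted
mean of the aligned samples (sampling is uniform, so time-weighting would
change nothing but the edge samples).  Decline landmarks (2.5, 5, 10 pp
below peak) take the value-nearest sample at the first crossing after the
peak and are reported absent when saturation never falls that far — an
absent 10 pp landmark is itself informative (nearly half of Type A dives
never desaturate that much).

Desaturation interruptions follow a 4 pp rule: an **inflection** is a rise
strictly greater than 4 pp from a local minimum to the next local maximum
(4.0 pp exactly does not qualify); a **plateau** is a maximal run ≥ 30 s
whose net change lies in (−1, +4] pp with no sample-to-sample drop larger
than 1 pp.  The −1 pp floor, the 30 s minimum and the 1 pp step bound are
declared choices (observed plateaus average ~107 s).  No smoothing is
applied before detection — the native 5–15 s cadence is already coarse.
With measurement noise the rule also fires on small noise excursions at
low saturations, where the steep part of the dissociation curve amplifies
1 mmHg of electrode noise into >2 pp of saturation; detected interruption
counts under noise are therefore upper bounds, and only the noise-free
counts are checked exactly.

## Venous profile typing

The original classification was done by eye; the cascade below is a
declared formalization, so per-dive agreement with the authors' manual
labels cannot be asserted — only agreement with the generator's ground
truth is tested.

The deciding quantity is the **sustained-decline onset**: the earliest
sample after which saturation never again rises above (running peak −
10 pp).  Rules, first match wins:

1. minimum saturation ≥ 90% → **Type A** (arterialized throughout);
2. no onset: net peak-to-end decrease ≥ 2 pp → **Type A** (the decline is
   small and late), otherwise → **Other**;
3. onset at dive fraction ≥ 0.5 *and* inside the final ascent → **Type A**;
4. otherwise → **Type B** (an onset implies ≥ 10 pp of committed decline).

Two refinements deserve note.  First, a profile with *no* decline at all
(flat at, say, 50%) matches neither venous pattern: Type A profiles are
elevated or decline late, Type B profiles decline.  Rule 2's 2 pp floor
sends such profiles to Other rather than defaulting them to Type A.
Second, the onset is known only to sample resolution: the last "high"
sample can precede the true crossing by a full 15 s interval, so rule 3
evaluates position and phase at the onset's half-interval midpoint.
Without this, a late-ascent decline in a short dive is systematically
pushed one sample before the detected ascent and mislabelled Type B.

## Synthetic-data generator

The generator emulates the study conditions; its defaults are the printed
group statistics, not tunable knobs.  Per group: log-normal duration and
depth draws matching the printed means/medians (Type A 4.1/3.1 min,
27/24 m; Type B 9.3/9.0 min, 54/51 m; arterial 5.5/5.3 min, 30/23 m),
truncated at the 2 min inclusion floor plus the threshold-crossing loss;
trapezoidal depth profiles with drawn descent (0.8–1.3 m s⁻¹) and ascent
rates, optional mid-bottom sub-ice excursions (p = 0.35); and
piecewise-linear saturation trajectories:

* **arterial** — rise of ~2.5 pp over the first minute to a >99% peak,
  slow drift through the landmarks 96.6% @ 0.70, 94.5% @ 0.77, 89.2% @
  0.85 of dive time, end 77.9 ± 6%;
* **Type A venous** — rise of 11.4 ± 3.5 pp to a 94.1 ± 3% peak at
  fraction 0.40 ± 0.10, flat plateau, then a decline beginning inside the
  final ascent (fraction ≥ 0.58).  45% of dives draw a small decline
  (2–9.5 pp, mean 5.75) and 55% a large one (N(30.9, 8) truncated), so the
  population net decrease averages 19.6 pp and end-of-dive 74.5%;
* **Type B venous** — rise of 1.8 ± 1.2 pp to a 79.1 ± 6% peak within
  0.08 of dive time, decline past peak − 10.8 pp by fraction 0.18 ± 0.05,
  then a progressive decline to 31.1 ± 12% at the end, truncated so every
  dive declines ≥ 12 pp.

Dispersions are declared choices: printed dive-level spreads where the
text supports them, otherwise scaled to keep draws inside physical bounds.
The interruption dispersions printed as ±s.e.m. (15.1 ± 9.9 pp rise,
82 ± 50 s time-to-peak, 107 ± 56 s plateau) are arithmetically impossible
as standard errors at n ≈ 84–103 and are treated as standard deviations.

Interruptions are planted on Type B dives: count 1–3 with probabilities
53.8 / 32.3 / 12.3% (one dive in 65 gets none), 81.6% inflections, placed
on descent / ascent / at maximum depth with probabilities 48.4 / 28.1 /
23.4%.  Inflections are **dip-and-recover** events — an extra cosine
decline followed by a recovery toward the baseline, onset at the local
minimum — which matches the detection rule and lets descent-phase events
exist without exceeding the dive's peak.  Plateaus hold the baseline value
(rise ≤ 3.9 pp) and rejoin over 40 s.  Three guards keep planted truth and
detection in exact agreement at zero noise: events never overlap the
drawn-peak crest (held flat for 18 s ≥ one sampling interval so the sparse
record realizes the drawn peak exactly); events late in the dive stay
≥ 11 pp below the peak so they cannot mimic a Type A late decline; and
every planted event is re-verified against the noise-free sampled grid,
with unrecoverable bumps withdrawn.  Trajectories end with a ~12 s flat at
the drawn end-of-dive value so nearest-sample end readings are unbiased.

Base trajectories are piecewise-linear *without* smoothed joins: cosine
ramps at the terminal knot flatten the last ~45 s below the 1 pp/step
plateau criterion and plant spurious end-of-dive plateaus.  Cosine shapes
are kept for the interruption legs, where they cause no artifact.

P_O2 is the exact inverse-Hill transform of the trajectory plus additive
Gaussian noise (default σ = 1 mmHg), sampled at the logger cadence; depth
noise defaults to 0.  Each record draws from an RNG substream seeded by
`(seed, record index)`, making records byte-identical whether generated
alone or inside any dataset.

What the generator does **not** emulate: electrode drift and response
lag, gaps and dropouts, pH/temperature effects on the curve, between-bird
variance components (the printed tables do not let them be separated from
within-bird spread, so a single-level spread is used), realistic wiggly
depth profiles, or any mechanistic link between depth and saturation.
Passing tests therefore demonstrate that the pipeline recovers known
truth under the stated observation model — not that the classifier would
reproduce the authors' manual labels on the original recordings.  Known
sitting limitations: wide events rarely fit three-to-a-dive, so dives
with three interruptions are rarer than the target split, and planted
inflection rises average a few pp below the drawn magnitudes because the
underlying decline proceeds during the recovery.

## Pipeline and summaries

The orchestrated run applies: detection → segmentation → ODC conversion →
alignment → metrics → interruptions → typing (venous only) → group
summary.  Summaries are dive-weighted (matching the dive-level n's of the
source tables), report mean, s.e.m. (sd/√n) and median per variable, count
dives at or beyond the 5.6 min aerobic dive limit (inclusive), and exclude
'Other' dives as the study did.  The a-v difference series uses a fixed
assumed arterial saturation (95%) against the venous samples of the first
2 min of a dive.  The stats export emits one row per dive with natural-log
companions for duration, depth and the start-to-peak increase (NaN when
the value is non-positive; rows are never dropped), for mixed-effects
modelling in external tools — model fitting itself is out of scope here.

Everything is deterministic given the configuration (plus the seed when
simulating); repeated runs produce byte-identical CSVs.

## Problem sizes

The packaged analyses use 160-dive datasets (the study's group ratio) for
the worked example and 200 dives per group for the calibration checks —
the size at which a ±2 pp check on a group mean has comfortable power
given per-dive spreads of 3–12 pp.  A full 600-dive calibration run takes
on the order of seconds.
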