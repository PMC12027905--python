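# Methods

This note documents the models and numerical choices behind `oknpupil`: what
each pipeline stage assumes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Signals and trial structure

A trial lasts 9 s at 500 Hz (4500 samples): 3 s of static dots, then 6 s of
motion at 11.36 deg/s.  Two dot fields (white and black dots moving in
opposite directions within each field) flank a central fixation line; their
centres sit at ±15.225° (half the 12° separation plus half the 18.45° field
width).  A first auditory cue at motion onset directs gaze (overt condition)
or covert attention to one field; a second cue, uniformly 2.9–3.3 s later,
either repeats or flips the cued side, tracked motion direction and attended
brightness.  Two target numerals (0.83 s each) gate trial correctness; only
trials with both identified correctly enter group analysis.

## Preprocessing

* **Sentinel rule.**  Samples that are exactly `0` or greater than `100,000`
  are tracker failure codes (lost pupil during blinks, out-of-range
  position) and become missing.  A true physical position of exactly 0.0 deg
  would be lost too; on continuous data this has probability ~0.  Non-finite
  input is likewise treated as missing.
* **NaN-aware smoothing.**  Both smoothers (boxcar and Gaussian) drop weights
  over missing samples and renormalize over the rest, truncating the kernel
  at the trace edges.  Consequences: a constant trace is exactly preserved;
  smoothing imputes missing samples whose window contains data; a sample is
  missing after smoothing only if its whole window is.  The Gaussian kernel
  has length `window` and σ = `window/5` (the common default of numerical
  environments that specify Gaussian smoothing by window size); windows are
  counted in samples (at 500 Hz: 11 ≈ 22 ms, 100 ≈ 0.2 s, 500 ≈ 1 s,
  1000 ≈ 2 s).
* **Pupil z-scoring.**  Per trial, over the full 9-s presentation window:
  subtract the mean and divide by the SD (ddof = 1) of the non-missing
  samples; applied after the window-100 smoothing (smoothing, then
  normalization).  Trials with fewer than 2 valid samples or zero variance
  raise `DegenerateTrialError` and are excluded from averaging and logged.
* An optional ±50 ms pad around missing runs (`pad_missing_runs`) guards
  against half-occluded samples at blink edges; it is off by default because
  blink detection proper is delegated to the eye tracker's own algorithm.

## Slow-phase velocity reconstruction

Order of operations: 11-point moving average on position → central
differences → 11-point moving average on velocity → saccade detection →
excision + linear interpolation → window-1000 Gaussian smoothing.

* **Derivative convention.**  `v[i] = (x[i+1] − x[i−1]) · f_s/2` interior,
  one-sided at the two edges; a derivative touching a missing sample
  (including the centre one) is missing.
* **Saccade detection.**  Candidate events are interior local extrema of the
  smoothed velocity with `|v| > 20` deg/s (plateaus contribute their first
  sample — deterministic tie-break).  Each extremum is expanded outward to
  the flanking extremum of opposite type: from a positive peak, walk while
  the velocity is non-increasing; from a trough, while non-decreasing; then
  retreat across the final equal-valued run to its sample nearest the peak,
  so flat stretches beyond the true flank are not swallowed.  Walks stop at
  trace edges and missing samples.  Overlapping or adjacent spans are merged
  (union), making excision idempotent.  The flanking-extremum reading (rather
  than a minimum of |v|) matters quantitatively: |v| minima sit at the zero
  crossings inside the velocity transition of each quick phase, which would
  leave sub-threshold ramp residue and bias the reconstructed slow-phase
  speed ~10% toward zero.
* **Excision.**  Saccadic spans and pre-existing missing samples are replaced
  by linear interpolation between the nearest finite neighbours;
  leading/trailing gaps extend the nearest value (no outer anchor exists).
  Gaze-shift refixation saccades exceed the threshold and are excised by the
  same rule — no separate handling of the field geometry is needed.
* The output trace is fully finite; on noise-free synthetic input the
  steady-state reconstruction is accurate to ~10⁻⁴ relative (the acceptance
  script measures this).

## Latency estimation

The latency of a response to the second cue is the time of the deepest local
minimum of the smoothed *acceleration* of the underlying signal within
±1.5 s of the cue.  Derivatives are central differences in physical units;
the acceleration is smoothed with a window-500 Gaussian (σ = 1/5 window).
`diff_order` states how many derivatives reach acceleration: 2 for
position-like input (z-scored pupil size), 1 for slow-phase velocity (already
a first derivative of gaze position).  This per-signal convention is what
makes the estimator land on the underlying response transition: the
acceleration of a smooth sigmoidal velocity switch has its valley at the
transition centre, and a first-order pupil constriction onset contributes a
negative delta to pupil acceleration exactly at the switch.  Differentiating
a velocity trace twice instead would locate the valley of the *jerk*, which
for any smooth monotone transition sits ~0.5 s away from the transition
centre once the window-1000 and window-500 smoothings (σ ≈ 0.4 s and 0.2 s)
are folded in — a systematic bias, not a noise effect.

Valleys must be strict local minima of the full trace; window-boundary
samples are not eligible.  If no valley falls inside the window the estimate
is explicitly invalid (excluded from group statistics and counted in the
log).  A numerically flat acceleration — e.g. from an exactly linear input,
whose derivatives are rounding dust — is also invalid; the flatness tolerance
scales with the input range so the estimator stays invariant under amplitude
scaling.  Valid latencies are bounded by the ±1.5-s window by construction.

Latency is computed per participant on cue-aligned averages (each trial's
trace is shifted so its second cue lands on the nominal cue time, then
averaged; residual missing samples are bridged linearly).  OKN traces are
sign-aligned before averaging (multiplied by the first-cue motion direction)
so the pre-switch slow phase is positive for every trial; the analysis is
restricted to the black→white opposite-cue trials, where both signals carry
a clear second-cue transition.  Per-trial latency is available through the
same function but is not the default.

## Group statistics

* Pointwise trace comparisons are **paired** across participants (all factors
  are within subject); an independent-samples variant is available.
  Zero-variance timepoints with zero mean difference give t = 0, p = 1.
* **Benjamini–Hochberg**: step-up over all m timepoints at q = 0.05;
  `p_thresh` is the largest p(k) with p(k) ≤ (k/m)·q, reported per panel;
  the significance mask is `p ≤ p_thresh`.  When nothing passes, `p_thresh`
  is 0 and the mask empty.
* The OKN-vs-pupil **latency comparison** is a pooled-variance two-sample
  t-test with df = n₁ + n₂ − 2, treating the two latency samples as
  independent groups.
* **Correlations** are Pearson r with two-sided p; pairs with any invalid
  latency are dropped and n is reported.  n is data-driven (participants can
  drop out through invalid estimates); nothing is imputed.

## Synthetic generator

The generator reproduces the study design (participants × 2 conditions ×
blocks × 16-trial full factorial of motion direction × brightness × cue side
× cue relation, randomized within block) with known ground truth per trial:

* **OKN.**  Slow-phase velocity tracks the cued motion at gain × 11.36 deg/s
  (gain 1.0 overt, 0.4 covert — covert OKN is reliably weaker).  Each cue
  switches the tracked direction through a smooth sigmoidal transition
  centred at `cue + okn_latency`.  The transition is a raised cosine with
  compact support, matched to a 90% point 0.25 s from the centre; a logistic
  of the same half-width was rejected because its infinite tails leave every
  noise-free plateau monotonically sloped at float precision, which defeats
  any discrete local-extremum saccade rule (and is an artifact of exact
  arithmetic, not a property of real data).  Quick phases are linear resets
  of amplitude A = 2 deg over 40 ms, triggered whenever the accumulated
  slow-phase eccentricity from the fixation locus exceeds A; the trigger
  bookkeeping treats each reset as instantaneous, so a noise-free trace
  contains exactly ⌊total slow displacement / A⌋ quick phases.  A is a free
  modelling choice (the OKN amplitude/frequency is not constrained
  numerically by the study design); 2 deg at unit gain yields ~5.7 quick
  phases/s, a realistic stare-nystagmus rate.
* **Gaze vs attention.**  In the gaze condition the fixation locus steps to
  the cued field centre via a single 30-ms refixation saccade 0.2 s after
  each side-changing cue; under covert attention the locus stays at 0°.
  Vertical position is low-amplitude noise only — the analyses are
  horizontal.
* **Pupil.**  First-order relaxation `τ ṗ = p∞(t) − p` with τ = 1 s toward a
  brightness-dependent asymptote (baseline 100 px, ±20 px for black/white),
  switching at `cue + pupil_latency`; integrated by the exact per-sample
  exponential update, so a single step matches the closed-form solution to
  machine precision.  Covert attention scales the step by 0.4 and adds a
  +1 px/s linear drift (cognitive-load dilation).
* **Ground-truth latencies** are drawn once per participant: OKN ~
  Normal(0.4 s, 0.15 s); pupil ~ Normal(0.9 s, 0.2 s) truncated to
  (0, 1.4) s, keeping injected valleys inside the ±1.5-s search window and
  preserving the empirical ordering pupil latency > OKN latency at the group
  level.
* **Artifacts.**  Blinks arrive at 0.15/s (Poisson count, uniform placement,
  100–300 ms, overlapping draws discarded): within a blink the pupil reads
  exactly 0 and both position channels 150,000 — precisely the pathologies
  the sentinel rule targets.  Gaussian measurement noise (0.05 deg position,
  0.5 px pupil) is added everywhere else.  `both_correct` is Bernoulli per
  condition (0.9382 gaze, 0.5699 attention), sampled independently of signal
  quality — modelling the attention–correctness coupling is out of scope.

**What the generator does not emulate:** anticipatory slow-phase decline
before the second cue, OKN frequency/amplitude variability and after-
nystagmus, pupil foreshortening with eccentric gaze, smooth drifts and slow
tracker offsets, torsional components, and any dependence of correctness on
signal quality.  Passing recovery tests therefore demonstrates that the
pipeline is correct and unbiased for the modelled signal class, not that it
is robust to every artifact of real recordings.

## Problem sizes and determinism

Validation runs use desk-scale sizes chosen to exercise every code path:
cohorts of 3 participants × 1 block for recovery (50 seeded cohorts), 200
runs for the null-FDR check, 200 traces for the latency-window bound.  All
randomness flows from explicit integer seeds through numpy `SeedSequence`
spawning; a fixed seed reproduces sessions bit-identically, including
through the CSV round-trip (floats are written with `%.17g` and parsed in
round-trip mode).

## Known limitations

* The saccade-detection walk assumes velocity noise is small relative to the
  20-deg/s threshold after the 11-point smoothing; heavy noise would
  fragment flanks (real pipelines mitigate this the same way, via the
  smoothing).
* Latency estimates on same-cue trials are typically invalid by design
  (there is no second-cue transition); group analysis uses opposite-cue
  trials.
* With very few participants the BH threshold per panel is conservative and
  correlations are underpowered; n is reported so the caller can judge.
* The reader for real exported sessions expects the package's own CSV
  layout; adapting a specific tracker export is a documented extension
  point (`oknpupil.io`).
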