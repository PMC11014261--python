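# Methods

This note documents the models implemented by `jurysense`, their
assumptions, the defaults and why, and the design choices made where the
underlying procedure left genuine freedom.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Affect metrics

Each frame carries softmax-normalised percentages for Ekman's six
universal emotions.  Valence and engagement are the linear functionals

```
valence    = H − Sa − A − F − D
engagement = H + Su + A + F − Sa
```

Both are linear on the emotion simplex, so their extrema sit at vertices:
valence spans exactly [−100, 100] (pure happiness / any pure negative
emotion) and engagement peaks at 100.  The engagement formula is *not*
bounded below by 0 (pure sadness gives −100); since engagement is defined
as a deviation-from-neutrality score on [0, 100], the reported value is
clipped at 0 while `engagement_raw` retains the signed value.  Whether the
original pipeline clipped or simply never observed negative values is
unknowable from the outside; clipping honours the published range without
destroying information.

An optional `neutral` channel is accepted: it participates in the
sum-to-100 constraint and is ignored by both formulas, which is compatible
with both a six-channel and a seven-channel softmax front end.

## Attention classifier

Head pose is proxied by distance ratios on the 68-point landmark scheme,
not by true rotation angles:

* `yaw = |d(2,31) / d(31,16)|`, folded by the reciprocal into (0, 1]; 1
  means a bilaterally symmetric (frontal) face.
* `pitch = d(28,31) / d(37,40)`, falling back to `d(43,46)` when the left
  eye width is degenerate.  The source description is ambiguous about the
  direction of this ratio (prose and pseudocode are reciprocals of each
  other); nose-bridge-over-eye-width is used because only that direction
  can exceed the printed threshold of 5.
* `ear`, the blink-detection eye aspect ratio, averaged over both eyes
  with a single-eye fallback.  Which eye (or combination) the original
  tool used is unstated; averaging is the symmetric choice.

Decision rule (defaults: yaw 0.4, pitch 5, EAR 0.10):

* **ear_guarded** (default): attentive iff `yaw ≥ 0.4` and *not*
  (`pitch > 5` and `ear < 0.10`).  The pitch gate fires only together with
  a low EAR, so ordinary blinks (low EAR, normal pitch) never flag
  inattention — the stated purpose of combining EAR with pitch.
* **literal**: attentive iff `yaw ≥ 0.4` and `pitch < 5`.  This preserves
  the alternative reading of the published pseudocode, whose line order
  would otherwise let the pitch test overwrite the yaw result.

Boundary semantics follow the printed comparisons: yaw exactly 0.4 is
attentive, pitch exactly 5 does not fire the guarded gate, and the gaze
window (1, 25) cm is strict on both sides.  Only the horizontal gaze
coordinate is thresholded (vertical gaze is too inaccurate to use); a
missing gaze sample passes face attention through by default
(`gaze_missing_policy`).  Frames with degenerate geometry (zero reference
distances) are flagged invalid and treated as no-face frames by cleaning.

All three features are ratios of Euclidean distances, hence exactly
invariant under translation, in-plane rotation, uniform scaling and
mirroring of the landmark set — verified by property tests.

## Session model

* **Schedule.**  The AB–BA design presents every unordered pair of the
  `n` sounds twice, once per order: `n(n−1)` comparisons (42 for 7
  sounds).  Stimulus durations are not part of the published design;
  defaults are 10 s per sound and a 1 s inter-pair gap, both
  configurable.  Windows are half-open `[start, end)` so every frame lands
  in at most one sub-segment.
* **Cleaning** drops frames with missing emotion or attention values and
  frames outside the session window (jurors sitting down / standing up);
  it is idempotent and order-preserving.
* **Smoothing** is a centred moving average with truncated edges (no
  padding invented at the boundaries).  The window length is a free
  parameter; the default of 28 frames is ~2 s at the 14 fps processing
  rate — long enough to suppress frame noise, short enough to keep
  sub-segment trends.  Boolean attention smoothed the same way yields the
  attentive fraction in [0, 1], banded for display at >0.8 (attentive) and
  <0.2 (inattentive) with strict inequalities.

## Choice inference

For each sound sub-segment, ordinary least squares of valence on time
gives slope, R² and the Pearson correlation ρ (computed with population
standard deviations; the N vs N−1 factors cancel, so the convention is
immaterial, and ρ² = R² identically for simple regression).  Constant
valence returns the degenerate convention slope 0, R² 0, ρ 0.  Trends are
fitted on cleaned, *unsmoothed* valence by default — smoothing is
presentational.

The choice criterion is stated for one rising and one falling trend:
rising valence → the higher-quality answer, falling → the more-annoying
answer.  Real segment pairs frequently have same-sign slopes, so the
implemented rule orders by slope (larger slope → q2 choice, smaller → q1
choice), the minimal generalisation consistent with scoring same-sign
pairs; `require_opposite_signs=True` restores the strict reading by
abstaining otherwise.  Comparisons abstain when either sub-segment has
fewer than `min_frames` frames (default 5) or the slopes differ by at
most `slope_tie_epsilon` (default 0, exact ties only).

**Reliability correlation.**  The Spearman correlation is computed between
the juror's actual answers, encoded +1 = chose second / −1 = chose first,
and the trend-derived prediction for the same comparisons.  The exact
vectors used by the original Matlab `corr` call are not published, so the
encoding is a documented choice here: by default the prediction is the
*sign* of the slope difference (second − first, negated for q1 so a
criterion-consistent juror scores +1 on both questions).  The sign
encoding is the default because it makes "juror follows the criterion
perfectly" map to exactly ρ = 1; correlating the raw slope difference
against a ±1 answer vector cannot reach 1 even under perfect concordance
(midrank ties in the binary vector cap the rank correlation), which would
make the natural calibration point unattainable.  The raw-difference
encoding remains available (`trend_encoding="difference"`).  Ties use
midranks; missing answers drop the comparison pairwise; fewer than three
usable comparisons flags the variant as insufficient (NaN, excluded from
cohort curves).

With the attention filter, every trend is refitted on frames classified
attentive, and comparisons left with fewer than `min_frames` attentive
frames in either sub-segment are dropped from both vectors.  The
juror-count-vs-threshold curve counts, per threshold τ, jurors with
ρ ≥ τ for each variant; it is non-increasing in τ by construction.

## Questionnaire analysis

Self reports give one concentration state per period (beginning, during,
end).  How the original study aligned periods to frame timestamps is
unstated; the default splits the cleaned session span into equal thirds,
configurable to schedule-based boundaries.  Per juror and period the
Boolean attention stream is averaged; a juror reporting the same state in
several periods contributes the mean of those period means.  Cohort cells
report the median across contributing jurors.  Baseline deltas subtract
each juror's *fully focused* attention from every other state (jurors who
never reported the baseline state are excluded), and the reduction
fraction per state is the share of contributing jurors with a strictly
negative delta.

## Synthetic data generator

The study's recordings are private, so the generator produces sessions
with the statistical structure the analysis assumes.  What it emulates,
and how:

* **Face geometry.**  A fixed, bilaterally symmetric 68-point 3-D template
  (built from explicit coordinates, versioned with the package) is rigidly
  rotated by per-frame yaw/pitch angles, orthographically projected and
  scaled to pixels.  At the frontal pose the projected landmarks give
  yaw ratio exactly 1 and EAR exactly 1/3; eyelid landmarks scale with an
  `eye_openness` parameter (0 collapses the eye, EAR 0).  The projected
  yaw ratio decreases strictly monotonically over head-yaw 0–60° and
  crosses the 0.4 threshold once (~40°).  *Validity limit:* beyond ~70°
  the projected nose tip crosses the jaw silhouette and the ratio becomes
  non-monotone; a real landmark detector loses the face well before that,
  so the generator keeps head turns within |yaw| ≤ 70° and the classifier
  guarantees are stated for that regime.
* **Attention process.**  A two-state Markov chain with ~42-frame (3 s at
  14 fps) dwells whose stationary attentive probability is set per period
  to (0.95, 0.70, 0.40) — the session-long decline in concentration.
  Inattention is rendered *physically*: the head turned 55–70° away and/or
  the gaze parked at 27–45 cm (off the 1–25 cm window), so the attention
  column of a generated session is produced by the classifier, never
  copied from the latent state.  Attentive frames carry small pose jitter
  and Poisson blinks (0.25 s⁻¹, 3 frames, openness 0.08) that the
  EAR-guarded rule must not flag.
* **Valence trends.**  Each sound has an intrinsic slope (default
  `linspace(−2, 2, n_sounds)` valence/s).  Within a sub-segment the latent
  valence follows that line, centred on the base valence at the segment
  midpoint, realised by moving mass between the happiness and sadness
  channels around a fixed base vector (H 30, Su 15, Sa 30, A 10, F 5,
  D 10; base valence −25); infeasible slopes (which would drive a channel
  negative) are rejected.  Per-channel Gaussian noise (sd 2 percentage
  points) is added, channels are clipped at zero and renormalised to 100.
  With zero noise the construction is exact: fitted slopes equal injected
  slopes to numerical precision.
* **Inattentive frames** express emotion *unrelated to the stimulus* — the
  premise that motivates attention filtering in the first place.  On those
  frames the stimulus-driven trend is replaced by a slowly wandering
  distraction valence, an AR(1) with stationary sd 25 valence units and a
  ~2 s correlation time.  An earlier design that merely added white noise
  on inattentive frames was found not to reproduce the filtering benefit:
  independent noise inflates slope variance far less than an
  autocorrelated, trend-free process, while filtering always costs time
  span, so the filtered fits could come out *worse*.  Decoupling is the
  faithful rendering of "emotion driven by events not relevant to the
  test", and under it attention filtering recovers the injected trends.
* **Answers** follow the slope criterion with probability `p_consistent`
  (default 0.9 — jurors are mostly but not perfectly introspective) and
  are otherwise uniform.  **Questionnaire states** derive from the
  realised per-period attention rate through fixed cut-points: ≥ 0.8
  fully_focused, ≥ 0.65 actively_involved, ≥ 0.5 partially_focused,
  ≥ 0.3 feeling_bored, below that distracted or heavy_eyed by a fair coin.
* **Cohorts** derive independent per-juror seeds from a master seed and
  jitter `p_consistent` (sd 0.05) and a common attention-rate factor
  (sd 0.05); `heterogeneity=0` disables the jitter.  Generation is a pure
  function of the spec: identical seeds give byte-identical sessions.

What the generator does **not** emulate: photorealistic appearance or
detector noise on landmarks, correlated emotion channels beyond the
happiness/sadness axis, order effects between the AB and BA presentation
of a pair, learning/fatigue effects on the answers themselves, and
non-stationary blink or gaze statistics.  Tests passing on synthetic
cohorts therefore validate the *pipeline's* correctness and the internal
consistency of the method, not the field accuracy of emotion recognition
on real faces.

## Numerical choices and problem sizes

* OLS via `scipy.stats.linregress`; degenerate inputs (fewer than two
  distinct timestamps) raise; constant valence returns the 0/0/0
  convention above.  Spearman via `scipy.stats.spearmanr` (midranks),
  cross-checked in tests against an independent rank-then-Pearson oracle.
* Metric extrema are confirmed by exhaustive grid search at 1% resolution.
  Because both metrics are linear with coefficients shared across
  channels, the search runs over per-coefficient group totals — provably
  the same image as the full six-dimensional grid — and is cross-checked
  against a linear-programming vertex oracle.
* Degenerate landmark geometry (zero reference distance, threshold 1e−9)
  raises `DegenerateLandmarkError` scalar-wise and is flagged invalid in
  the vectorised path.
* Test problem sizes: the end-to-end recovery suite uses a 40-juror
  cohort at full session size (7 sounds, 42 comparisons, 14 fps) under
  noise-free conditions, and 20 seeded single-juror sessions at default
  noise for the filtering-benefit check; the questionnaire consistency
  check uses 20 jurors at 2000 frames per period.  These sizes give
  sampling error far below the asserted margins while keeping the default
  suite fast.

## Known limitations

* The pitch ratio of the template geometry cannot exceed the threshold 5
  under pure pitch rotation (the numerator shrinks with pitch), so the
  pitch/EAR gate is exercised through direct feature-level tests rather
  than through rendered poses; in real data that gate captures downward
  head tilt where landmark detectors behave differently from a rigid
  projection.
* The Spearman encoding is a documented reconstruction, not the original
  tool's exact computation (unpublished); both plausible encodings are
  implemented.
* Period alignment of the questionnaire, stimulus durations and the
  smoothing window are free parameters here; published figures that
  depend on them (reduction percentages, juror counts at ρ = 0.7) are
  qualitative targets only, since the underlying recordings are private.
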