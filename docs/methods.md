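# Methods

## The entrainment model

A conversation is treated as a trajectory of a dyad-level feature point.
For each feature k (k = 1: mean f0; k = 2: f0 interquartile range) and
each speaker, the feature is summarised over the first and the last
third of the *elapsed* conversation time, giving a start point
S = (S1s, S2s) and an end point E = (S1e, S2e) in Hz² with the
participant always on axis 1 and the partner on axis 2. Thirds are
thirds of the timeline (the TextGrid's xmax), not thirds of accumulated
speech: silences and non-linguistic vocalizations are excluded from the
feature frames but not from the clock, because elapsed time is the only
division both speakers share. The middle third is deliberately unused —
the measure contrasts the opening and closing stretch of the
conversation.

Entrainment is scored geometrically against a register-matching
reference line through the origin:

* **l1** (slope 1): both speakers at equal f0. Used for every pairing
  except the one below.
* **l2** (slope ½): the lower voice one octave below the higher. Used
  only when an adult female partner talks with a teenage boy, the one
  speaker-class pairing whose comfortable registers sit roughly an
  octave apart. Internally the implementation records *which axis* is
  the halved (lower-register) one and exposes the effective slope in
  (participant, partner) space — 2.0 when the participant is the teen
  boy — so callers never reorder speakers. A pre-voice-change boy
  ("child" class) with an adult female partner stays on l1.

With d1 and d2 the perpendicular distances of S and E to the line
(|m·x − y| / √(m² + 1)),

    Δent = d1 − d2      (Hz; positive = convergence)

Per-speaker attribution uses the along-axis changes d3 = |S1e − S1s| and
d4 = |S2e − S2s|: responsibility resp_i = d_i/(d3 + d4), signed
contribution sign(Δent)·resp_i ∈ [−1, 1], adjusted contribution
Δent·resp_i (Hz; the two adjusted contributions always sum to Δent).
When neither speaker moved (d3 + d4 = 0) responsibility falls back to an
even 0.5/0.5 split and is flagged degenerate. If E crosses to the far
side of the line (overshoot), the literal d1 − d2 is reported; no
reflection correction is applied.

Classification: |Δent| ≤ 1 Hz (inclusive) is maintenance; above the band
Δent > 0 is convergence and Δent < 0 divergence. Separately, cohort
convergence counts use a strict > 2 Hz criterion. Both thresholds are
config-exposed and echoed into every summary. Because published
group-level Hz summaries can be read either as perpendicular distances
or as raw between-speaker gap changes, the pipeline exports an auxiliary
`gap_change` = |S1−S2|_start − |S1−S2|_end next to Δent.

## Feature extraction

Pitch tracks are frame-wise f0 at a 10 ms step with an explicit voicing
mask. The primary path consumes precomputed tracks (CSV `time,f0,voiced`
or Praat PitchTier, whose voiced points are snapped onto the regular
grid), so estimator choice can never silently change results. An
autocorrelation estimator is provided for raw audio: window of three
floor-periods, normalized autocorrelation searched over the
speaker-class band, interior peaks only, near-ties broken toward the
shortest lag (guards against octave-down errors), parabolic lag
refinement, voicing threshold 0.45. Class bands: children 100–450 Hz,
teen girls 100–400 Hz, teen boys 50–350 Hz; adult partners are not
assigned published bands, so adult female defaults to the teen-girl band
and adult male to the teen-boy band (configurable).

The linguistic filter clears the voicing mask outside the union of
intervals explicitly flagged linguistic. The flag is assigned once, at
parse time, by a configurable label-exclusion rule (default exclusions:
empty labels, `laughter`, `hum`, `stereotypy`, `noise`, `sil`, `sp`);
downstream code never re-inspects label strings. Interval membership is
half-open [start, end) at 1 ns tolerance so shared boundaries are never
double-counted. Simultaneous speech is retained for both speakers: each
tier is filtered independently against its own intervals.

Summaries use the arithmetic mean and the Q3 − Q1 IQR with
linear-interpolation quantiles. A window with fewer than `min_frames`
voiced frames (default 50, i.e. half a second of voicing) yields a
flagged missing feature; any missing window makes the dyad's feature k
unusable and it is excluded from downstream statistics with a log
record, rather than raising.

## Statistical layer

Three outcome families are modelled by OLS (statsmodels), each at the
dyad row level for the conversation outcome and at the participant level
for the contribution outcomes:

1. conversation entrainment: `delta_ent ~ group + age + celf_core +
   group:age`
2. entrainment contribution: `contribution ~ group + celf_core`
3. adjusted contribution: `adjusted_contribution ~ group + celf_core +
   group:age` (plus the age main effect, included so the interaction is
   well-formed)

These retained predictor sets are frozen as named specs rather than
re-derived by stepwise selection, for reproducibility. Each family also
fits a full model adding gender, non-verbal IQ and the conversation
partner (unordered categorical); with few conversations per partner that
factor is often aliased, in which case it is dropped with a warning (and
the full model omitted entirely if the sample cannot support it). The
f0-range family re-runs all three outcomes on the IQR feature (k = 2).
Group is treatment-coded with ASD as the reference level, so the group
term is the NT effect. p-values are two-sided from the t distribution
with residual df; incomplete rows are listwise-deleted and logged;
rank-deficient designs raise an error naming the aliased terms instead
of silently pseudo-inverting. One-way two-group comparisons use the
sum-of-squares ANOVA (identical to the squared pooled t), and two-group
effect sizes convert F statistics via d = sign·√F·√(1/n1 + 1/n2).

## The synthetic-dyad generator

The generator emulates a goal-directed conversation between a child/teen
participant and an adult female research assistant:

* **Turn structure**: alternating utterances of U(1, 5) s separated by
  pauses of U(0.5, 2) s, tiled into Praat-style tiers with empty-label
  gap intervals; utterances are labelled linguistic.
* **Registers**: per-class mean f0 (child 230, teen girl 220, teen boy
  140, adult female 200 Hz) with a 10 Hz between-speaker SD. Speaker
  class follows age and gender (under 13 → child; 13+ → teen girl/boy).
* **Programmed entrainment**: the dyad drift (target Δent, in
  perpendicular-distance Hz) is realised *in feature space*: the two
  speakers' last-third mean targets are moved so that the (S, E) pair
  yields exactly the requested distance change against the dyad's own
  reference line, with the total along-axis movement split by
  `responsibility_split` (default 0.5). Frames are then rendered as
  target + Gaussian noise (SD 5 Hz), with a linear ramp through the
  unused middle third. This construction makes the ground truth exact at
  zero noise — the acceptance oracle — rather than approximated from a
  continuous-time model.
* **Calibrated preset**: 12 dyads per group, 600 s conversations, group
  mean drifts −6 Hz (ASD) and +4 Hz (NT); CELF-5 core scores
  N(88, 12.43²) vs N(109, 11.56²), non-verbal IQ N(107, 9.8²) vs
  N(110, 9.05²), ages U(9, 15), 3 girls and 9 boys per group of 12, nine
  adult partners assigned round-robin. The per-dyad drift is additionally
  modulated by −0.26 Hz per CELF point above the group mean, encoding
  the negative language-ability association; this leaves group means
  unchanged in expectation.
* **Non-speech contamination**: ASD participants emit non-linguistic
  vocalizations (labelled laughter/hum/stereotypy) at 0.5 per minute,
  rendered at twice the speaker's register. A pipeline that skips the
  linguistic filter is therefore measurably biased — this is a designed
  test of the exclusion rule, and NT dyads are unaffected.
* **IQR feature**: generated flat by default (no programmed IQR drift),
  mirroring a null f0-range outcome; an `iqr_drift` knob widens
  last-third noise for power studies (approximate, via the normal
  IQR ≈ 1.349 σ relation).
* **Feasibility**: register pairs whose start point is too close to the
  line for the programmed convergence (which would cross the line), or
  whose end targets would fall near the class pitch floor, are redrawn
  from the same seeded stream; if no feasible pair exists the generator
  raises an infeasible-drift error. The redraw conditions registers, not
  drifts, so programmed ground truth is unaffected.

One seed governs all randomness (cohort seeds are spawned from the
master seed); identical seeds give byte-identical output files, and
every generated CSV records the master seed in a header comment.

What the generator does **not** emulate: real spectral content (pitch
tracks are targets + white noise, not tracked speech), turn-taking
latencies or backchannels, within-utterance intonation contours,
octave-jump tracking errors, or any correlation between age and
entrainment. Passing recovery tests therefore shows the *measurement
chain* is correct and unbiased under realistic noise — not that the
clinical effects themselves are reproduced from audio.

## Numerical and scale choices

* Problem sizes: recovery tests and the acceptance script use the
  calibrated preset (24 dyads, 600 s, 10 seeds); unit-level cohort tests
  use 4–8 dyads at 2–5 minutes, sizes at which every feature window still
  comfortably clears `min_frames`.
* TextGrid IO accepts both long and short text dialects (and UTF-16
  input), emits long format with 6-decimal times; round-trips are exact
  to 1 µs.
* Quantiles: linear interpolation (the numpy default), recorded here so
  IQR values are reproducible elsewhere.
* Distances and regression estimates are validated against independent
  oracles in the test suite: dense-sampling line-distance minimization
  (10⁻⁶ Hz), direct normal-equation solves (10⁻⁸), and the F = t²
  identity.

## Known limitations

* The half-matching line is applied only to the named teen-boy /
  adult-female pairing; other cross-octave pairings (e.g. adult male
  partners) default to l1 unless overridden.
* Responsibility is undefined when neither speaker moves; the 0.5/0.5
  fallback is a convention, flagged in the output.
* With 24 conversations and 9 partners the full regression model is at
  the edge of identifiability; the partner factor is dropped when
  aliased, so partner effects are only weakly testable at this scale.
* The estimator is a plain autocorrelation tracker without median
  filtering or octave-cost dynamic programming; it is validated on
  synthetic periodic signals, and the primary pipeline path deliberately
  consumes precomputed pitch tracks instead.
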