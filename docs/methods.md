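# Methods

## Scope and units

All times are seconds internally; asynchronies are converted to
milliseconds only at reporting. Syllable indices are 0-based in code and
1-based only in human-facing text. The pipeline consumes mono WAV audio,
Praat TextGrid interval tiers (long or short dialect, default tier name
`syllables`, empty or whitespace-only labels treated as silence), delimited
pose tables (`time_s`, `y`, further columns ignored unless configured), and
a cognate item table (`item_id, word, n_syll, target_idx, competitor_idx,
accent_mark`).

## Acoustic prominence metric

Per syllable we take duration *D* (exactly the boundary-tier interval),
peak f0 *F* (maximum voiced f0 whose frame center falls inside the
interval) and peak envelope amplitude *I* (maximum envelope sample inside
the interval). Each cue is z-normalized across the syllables of the
utterance using the sample (n−1) standard deviation; a zero-variance cue
maps to all zeros (a neutral cue rather than undefined values). The
composite score is the weighted sum S = W_F·z_F + W_I·z_I + W_D·z_D with
default weights (0.33, 0.33, 0.33); nomination is the argmax, exact ties
resolving to the earliest syllable. Nomination is invariant to common
positive scaling of the weights (so 0.33 vs 1/3 is immaterial) and to any
affine transform of a raw cue across syllables.

**Missing f0.** A wholly unvoiced syllable has no peak f0. Its f0 z-score
is set to the minimum z-score among the utterance's voiced syllables —
absence of voicing must not win prominence — and the trial is flagged
`f0_missing`. With fewer than two voiced syllables the f0 cue is neutral
(all zeros) and the trial flagged.

### Envelope

Magnitude of the analytic (Hilbert) signal, low-passed with a zero-phase
4th-order Butterworth filter at 12 Hz, sampled on a uniform 100 Hz grid.
The 12 Hz cutoff removes the within-period ripple of voiced speech while
preserving syllable-rate amplitude structure; this is the standard envelope
recipe in movement–speech coupling work. The speech anchor for timing is
the local maximum of this envelope inside the nominated syllable (not
necessarily the word-global maximum).

### f0 tracker

Frame-wise normalized autocorrelation (FFT-based), 40 ms frames, 10 ms hop,
search range 75–500 Hz (covers adult mixed-sex speech), parabolic
interpolation of the autocorrelation peak, voicing decided by an
autocorrelation-peak threshold of 0.45 plus an RMS silence floor. These are
declared defaults, not estimates of any particular reference recording
chain; all are configurable.

## Kinematics

Raw vertical index-finger position is linearly resampled to a uniform
50 Hz, oriented so extension (downward motion; image-style `y_down`
coordinates already point this way) is positive displacement from the
trial-initial baseline (mean of the first 200 ms), and smoothed with a
zero-phase 4th-order low-pass at 10 Hz — well above the energy of a single
biphasic beat. Optional body-scaling divides by a configured reference
length; timing is scale-invariant, so this affects only amplitude units.
The apex is the time of the global maximum of the smoothed extension
displacement within the search window (full trial by default; optionally
speech interval ± 500 ms). An apex on the window edge is flagged
(`apex_at_window_edge`), not rejected. Movement presence (QC for the
blocked design) is a simple threshold on peak extension (default 0.3 in
preprocessed units).

## Trial analysis

Production class: `correct_L2` if the nominated syllable is the foreign-
language target, `incorrect_L1` if it is the distinct native-language
competitor, else `other`. Timing condition derives only from (matching,
sign of competitor−target distance, production class): matching + correct
is the baseline; mismatching + correct splits into `precede_correct` /
`follow_correct` by the competitor's position; mismatching + incorrect into
`precede_incorrect` / `follow_incorrect` by the target's position relative
to the produced (competitor) anchor. `other` productions and matching-
incorrect trials are retained in the trial table with
`condition = excluded` and omitted from the timing models. Asynchrony is
(apex − envelope peak) × 1000 ms, negative when the hand leads. A
phonologically anchored variant recomputes the speech anchor inside the L2
target syllable regardless of nomination, giving an analysis independent of
the produced prominence cues.

## Statistical models

Timing outcomes use identity-link linear mixed models (estimates are in
ms); the binary accuracy outcome uses a logistic mixed model. All models
carry crossed random intercepts for speaker and item, implemented in
statsmodels as variance components over a single all-inclusive group; the
structure is configurable. The condition model uses a cell-means
parameterization (`asynchrony ~ 0 + condition`), so each term is directly a
condition's estimated mean. The gradient model regresses asynchrony on the
signed syllable distance (competitor − target) over mismatching correct
trials; distance is measured in syllables (a declared choice — millisecond
distance would be an alternative predictor). The logistic accuracy model is
fitted by variational Bayes (`BinomialBayesMixedGLM`); estimates are
posterior means, SEs posterior SDs. p-values use the large-sample normal
approximation everywhere, avoiding dependence on any particular
degrees-of-freedom recipe, and are judged against an adjusted alpha of
0.016 (0.05 over three confirmatory questions) by default. A fit that the
mixed solver cannot complete (e.g. degenerate zero-variance inputs) falls
back to OLS on the fixed design and is flagged `converged = False` rather
than failing silently; in those degenerate limits the fixed effects
coincide.

## Synthetic studies

The generator emulates the four inputs with known truth:

* **Items.** 96 cognates: 48 matching, 48 mismatching (24 with a preceding,
  24 with a following competitor; distances ±1..3), half of each class
  accent-marked, word lengths 2–5 syllables. Mismatching items are 3–5
  syllables so an `other` production always has a residual syllable.
* **Audio.** Each syllable is an amplitude-modulated harmonic complex
  (8 harmonics, 1/h amplitudes, 16 kHz) with a Hann AM bump peaking at the
  syllable midpoint and a flat-plus-peak f0 contour. Speaker f0 baselines
  are drawn from two bands (~115 / ~215 Hz), emulating a mixed-sex sample
  and stressing the within-utterance z-normalization. The produced-stress
  syllable gets ×1.5 duration, +25% f0 peak and ×1.8 amplitude over
  lognormal per-syllable jitters (8% / 4% / 10%) — clearly hyperarticulated
  stress, so nomination on clean audio is nearly deterministic and
  production accuracy enters through the produced-stress draw (presets
  0.60 matching-correct; 0.53/0.27/0.20 mismatching), not through acoustic
  ambiguity. Base syllable duration is 0.16 s, keeping a full study's audio
  cheap to synthesize and analyze.
* **Movement.** Minimum-jerk extension–flexion displacement (0.3 s per
  phase, ~320 px amplitude at a 400 px reference length) in image
  coordinates with 2 px tracking noise, sampled at 50 Hz. The apex is
  placed at (produced-syllable AM peak + generated asynchrony), where the
  generated asynchrony is condition mean + speaker intercept + item
  intercept + trial noise (defaults −48/−88/+45/−119/+72 ms; SDs 40/30/120
  ms), or slope × signed distance (−77 ms/syllable) in gradient mode.
  Draws that would push the apex outside the pose span are clamped and
  flagged in the truth ledger (a ≥4σ event at defaults). Excluded-condition
  movement trials use the baseline coupling mean. Movement trials multiply
  the stressed syllable's amplitude by 1.15 (the biomechanical intensity
  boost).
* **Design.** Per speaker, each item occurs once per movement condition;
  conditions are blocked in runs of six with the block order alternating.
  Identical configs (including seed) give byte-identical datasets; the
  truth ledger records every per-trial draw.

**Native-speaker preset.** For verifying the metric itself, native trials
place stress always on the phonological target but with much larger cue
variability (22% / 16% / 35%) and smaller base boosts, so the metric agrees
with phonology well above chance but below ceiling — as real speakers'
variable cue use produces. The boost scale is calibrated by Monte-Carlo
bisection of end-to-end pipeline agreement to a target of 0.70.

**What passing tests do and do not show.** The generator produces clean,
stylized signals: no segmental structure, no coarticulation, no pose
occlusions or tracking dropouts, voicing everywhere, exact boundaries. Tests
against it demonstrate that the measurement chain is correct and that the
mixed models recover known effects at the study's size and noise level —
not that the acoustic metric or apex detector would reach the same accuracy
on real recordings, where forced-alignment error, creak, and tracking noise
all intrude. The verification-agreement preset quantifies metric accuracy
only under the preset's cue-variability assumptions.

## Numerical choices

Flat maxima (envelope, scores, displacement) resolve to the earliest
sample. Envelope values are clipped at zero after zero-phase filtering.
Inferred pose rates snap to the nearest integer when within 1e-6 relative
tolerance (so a uniformly sampled 50 Hz table reports exactly 50). Apex and
envelope-peak times are sample-grid times (no sub-sample interpolation):
at 50 Hz / 100 Hz this adds ±10/±5 ms uniform quantization noise per trial,
which is zero-mean and negligible against the 120 ms trial noise. The
acceptance computations run the default 26 × 96 × 2 design (~10,000 trials
over the two studies), with audio rendered at 16 kHz and 0.16 s base
syllables.

## Known limitations

* The TextGrid reader handles interval and point tiers of the two text
  dialects, not the binary or collection formats.
* The f0 tracker is a plain autocorrelation method without octave-cost
  dynamic programming; on real creaky or noisy speech a dedicated tracker
  would be preferable, and the `PitchTrack` interface accepts one.
* The logistic GLMM's variational posterior SDs are known to be slightly
  optimistic; for the large-n designs used here this does not change the
  null/significant calls at alpha 0.016.
* Item-level "other" productions place stress uniformly over the residual
  syllables; no sub-distribution is modeled.
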