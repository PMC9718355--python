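# Methods

## The analysis

`scdecode` asks, window by window, how much information about the
direction of an upcoming (or just-executed) saccade is carried by the
simultaneous activity of a small laminar population in the superior
colliculus (SC). A delayed-saccade session presents one of eight
targets, radially equidistant at 45° spacing; on each trial the animal
fixates, the target appears, a randomized delay (600–1500 ms) elapses,
and a saccade is made. Spiking activity and local field potentials
(LFPs) are recorded on the same 6–17 channels.

The decoding pipeline is:

1. **Features.** Summed spike counts or mean LFP voltage per channel in
   100-ms windows sliding by 10 ms, aligned to target onset or saccade
   onset. Windows are causal: the feature for a window ending at *t*
   summarizes `(t − L, t]` only, and results are plotted/indexed at the
   window end. Only *functional* channels enter the analysis: peak
   trial-averaged smoothed rate (10-ms Gaussian kernel) in the visual
   or motor epoch must exceed the baseline rate by more than
   20 spikes/s.
2. **Classifier.** Per window, an independent multiclass classifier:
   one-vs-one error-correcting output codes over all 28 class pairs,
   each pair a two-class linear discriminant with pooled within-class
   covariance whose inverse is the Moore–Penrose pseudoinverse
   ("pseudolinear" LDA). The pseudoinverse is essential for spike
   features: a channel with no spikes in a 100-ms window has zero
   variance, which would make a plain LDA fit singular; here the
   direction simply receives zero discriminant weight. Decoding is by
   pairwise vote, ties broken by summed signed margins, then by the
   lowest class index. Priors are empirical training frequencies.
3. **Scoring.** Per-class F1 on a held-out 30% of trials, averaged over
   10 random unstratified 70/30 splits (pooled across targets). A
   degenerate split that loses a class from training is resampled (at
   most 20 retries) before the iteration is skipped.
4. **Null.** The same procedure with target labels permuted
   independently before every split iteration. With eight equiprobable
   targets this lands at the theoretical chance of 1/8 = 12.5%.
5. **Baseline subtraction.** Each target's trace is reduced by its mean
   performance in windows ending 400–200 ms before target onset.
   Saccade-aligned traces have no pre-target windows, so they borrow
   the constants from the same session/modality's target-aligned
   series (the only baseline definition in the design).
6. **Epochs and tuning.** Five epochs summarize each target's
   subtracted trace: baseline (mean, −400..−200 ms target-aligned),
   visual (max, 100..200 ms target-aligned), early delay (mean,
   250..450 ms target-aligned), late delay (mean, −300..−100 ms
   saccade-aligned), motor (max, −50..+50 ms saccade-aligned; the
   peri-saccade search range is configurable since "near saccade
   onset" fixes no bounds). Per-epoch values across the eight targets,
   rotated so each session's preferred target sits at position 1, form
   a tuning curve. Its trapezoidal area over the open target axis 1..8
   (AUC, no wrap-around closure) measures total information; the AUC
   after additively shifting the curve so the preferred value is
   exactly 1 (normalized AUC) measures breadth, invariant to uniform
   offsets.
7. **Sweeps.** Window lengths {20, 50, 100, 200, 300} ms (10-ms slide
   throughout) and population sizes 1..U, the latter with uniformly
   random channel subsets redrawn per bootstrap (50 by default) and
   reused identically for the spike and LFP classifiers so the two
   modalities are matched channel-for-channel.
8. **Statistics.** Paired two-tailed t tests across sessions with star
   levels \*, \*\*, \*\*\* at p < 0.05, 0.01, 0.001, uncorrected (an
   optional Holm flag exists but is off by default, matching the
   uncorrected reporting convention). Degenerate zero-variance
   differences map to p = 0 (nonzero mean) or p = 1 (identical).
   The visuomotor index (V − M)/(V + M) — V and M the
   baseline-subtracted visual- and motor-epoch rates clipped at 0 —
   orders channels along the sensory–motor continuum and splits them
   into terciles; the formula is declared here because the "standard"
   index is conventionally this contrast ratio, with positive = more
   visual.

## The synthetic generator

No recorded sessions ship with the package; the generator produces
sessions with the statistical structure the analysis assumes, so every
stage is testable end-to-end.

- **Direction tuning.** Gain `exp(−Δ²/(2w²))` with Δ the circular
  difference between target direction and the channel's preferred
  direction. The gain is symmetric in ±Δ: a single channel cannot tell
  +45° from −45° targets — the ambiguity that motivates population
  decoding.
- **Rate model.** Baseline + tuned visual burst (Gaussian kernel,
  onset-gated at 50 ms, peak 100 ms, s.d. 20 ms post-target) + tuned
  tonic delay activity (200 ms post-target until 100 ms pre-saccade) +
  tuned motor burst (Gaussian, s.d. 17 ms, centered on saccade onset),
  plus an *opposite-field* term: a signed, per-channel rate change
  weighted by `(1 − gain)` and locked to the burst kernels, so targets
  far from the preferred direction elevate some channels and suppress
  others. Because its sign is mixed across channels, populations (but
  not single channels) can discriminate anti-preferred targets. The
  term is event-locked rather than tonic by design: a tonic offset
  would make the pre-target baseline itself decodable, which the task
  structure rules out (no target information exists before target
  onset). Rates are clipped at 0.
- **Spikes.** Inhomogeneous Poisson, implemented by discretizing the
  rate at 1 ms, drawing a Poisson count per bin and placing spikes
  uniformly within the bin. For the smooth kernels used this matches
  the exact integrated-rate Poisson law far below the resolution of
  any test here.
- **LFP.** Per-channel evoked negative deflections (Gaussian, s.d.
  30 ms) at the visual latency and at saccade onset, amplitude scaled
  by the same tuning gain; a small (5% of amplitude) tuned sustained
  delay deflection; white Gaussian noise (30 µV s.d. by default). This
  is deliberately the simplest model with the needed properties —
  strongly tuned transients, weakly informative delay — not a
  biophysical LFP model: no 1/f background, no volume conduction, no
  cross-channel correlation.
- **Heterogeneity.** Per-channel preferred directions are jittered
  (s.d. 10°) around the session preferred direction; tuning widths
  (35–55°), baseline rates (5–15 spikes/s), visual/motor gains
  (40–80 spikes/s), delay gains (5–15 spikes/s), opposite-field
  modulations (±10 spikes/s, mixed sign) and LFP amplitudes (30–60 µV)
  are uniform draws. These magnitudes are plausible for SC visuomotor
  neurons but are not fit to any recorded animal; they are exposed in
  `SessionConfig` / `sample_channels` overrides.
- **Timing.** All times in ms relative to target onset; trial window
  [−600, saccade + 400] ms; delay uniform over `delay_range` (default
  700–1500 ms); reaction time uniform 150–250 ms; LFP at 1 kHz.

What passing tests on this generator do **not** show: robustness to
non-Poisson spiking (bursting, refractoriness), correlated noise across
channels, electrode drift, eye-movement artifacts, or LFP spectral
structure. They do show that the pipeline's inference machinery —
windowing, pseudoinverse LDA/ECOC, F1 scoring, null calibration,
baseline subtraction, epoch/AUC extraction, sweeps — behaves correctly
on data whose ground truth is known.

## Numerical and design choices

- **Window convention** is left-open/right-closed `(end − L, end]`; a
  spike exactly at the window end belongs to that window. Counts over a
  partition of a trial therefore sum exactly to the trial's total.
- **Missing windows.** A target-aligned window that a short-delay trial
  cannot contain is dropped for that trial only; each window's
  classifier uses every trial that possesses it. A window missing any
  class entirely is left NaN, never silently zero.
- **Pseudoinverse cutoff** is `rcond = 1e-10` relative to the largest
  singular value; the 28 pair covariances are pseudoinverted in one
  batched call per fit.
- **Random streams.** Every window derives its generator from
  (master seed, alignment, modality, shuffled-flag, window end time),
  so any window is reproducible in isolation and reordering windows
  permutes the output exactly. All session-level randomness flows from
  `SessionConfig.seed`.
- **F1 convention**: undefined precision/recall (class never predicted
  and/or absent from the test split) scores 0, penalizing collapsed
  classifiers rather than rewarding them.
- **LFP classification features are raw window means**; the
  0.5–250 Hz band-pass + 60 Hz notch conditioning is applied only when
  plotting traces.
- **Smoothing width**: the 10-ms Gaussian kernel width is interpreted
  as the standard deviation. This touches visualization and the
  functional-channel screen only.
- **Across-session aggregation** rotates target indices so each
  session's preferred target is Target 1 before averaging (mean ± SEM).
  For synthetic sessions the preferred direction is known from the
  generator; estimating it from data (e.g. microstimulation) is out of
  scope.
- **Problem sizes in the shipped tests**: the default session is 15
  channels × 800 trials; time-course checks use window grids restricted
  to the epochs they assert about (e.g. 61 windows spanning baseline
  through the visual period for chance calibration, 10 bootstraps for
  the population-size check, 50 trials/target for the tuning-width
  recovery runs). These are the package's chosen test conditions; the
  full-span, 50-bootstrap configuration is the library default.

## Known limitations

- The SC's topographic amplitude dimension is not modeled; the task is
  direction-only at fixed eccentricity.
- Only an LDA learner ships; the learner interface is pluggable
  (`evaluate_window(..., learner=...)`) so an SVM can be substituted,
  but none is provided.
- The generator's parameter magnitudes are defaults for a plausible
  regime, not estimates; conclusions about real recordings require real
  sessions supplied in the interchange format.
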