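# Methods

## Problem and model

The pipeline classifies short windows of a smartwatch heart-rate (HR)
stream into three affective states — negative, positive, neutral — for
children with ASD in an uncontrolled session (child programming a robot
with an avatar's help). Labels are produced semi-automatically from a
facial-expression recognition (FER) stream over the session video, with a
human annotator handling low-confidence clips. Because the underlying
video/HR recordings are not public, the package pairs the analysis with a
synthetic cohort generator whose ground truth is retained, so every stage
is testable.

## Synthetic cohort generator

Each subject's session is driven by a latent per-second affect process:
segments drawn i.i.d. over the three states with geometric dwell times
(support ≥ 1 s). This is the simplest process that yields contiguous
affect episodes of the kind a learning session produces (happiness after
success, frustration after failure). Defaults and rationale:

| parameter | default | unit | why |
|---|---|---|---|
| n_subjects | 9 | — | the emulated cohort size |
| duration_range_s | (480, 846) | s | the emulated session duration range |
| baseline_bpm_mean / sd | 96.8 / 8 | BPM | cohort mean HR calibration; 8 BPM between-child spread is typical resting-HR variation at this age |
| state_offsets | neg +12, pos −6, neu 0 | BPM | arousal raises HR under negative affect (fear/anger); mild decrease for calm-positive; sized so extremes land near the 62–124 BPM envelope |
| hr_noise_sd | 3 | BPM | beat-to-beat measurement jitter of wrist PPG at 1 Hz |
| sampling_rate_hz | 1 | Hz | typical smartwatch transmission cadence; configurable because the true device rate is unspecified |
| fps | 25 | frames/s | video frame rate |
| dwell_mean_s | 20 | s | affect episodes of tens of seconds match the session narrative |
| fer_accuracy | 0.8 | — | a realistic in-the-wild frame-level FER hit rate |
| confidence | Beta(8,2) correct / Beta(2,4) incorrect | — | confidence must correlate with correctness for threshold escalation to mean anything |

HR samples are clipped to [30, 220] BPM after noise for physiological
plausibility. Surprise and contempt are emitted only as recognizer noise:
no latent state maps to them, mirroring their absence from the 3-class
clustering.

What the generator does **not** emulate: PPG waveforms or heart-rate
variability, autocorrelated measurement error, slow drift in baseline HR
(fatigue, posture), FER errors that correlate in time (lighting, pose),
or annotator disagreement. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the stated statistical
structure — not field performance on real children.

## Annotation

- Clip length `nf = fps × window_s` must be integral; trailing frames and
  HR samples that do not fill a window are discarded (fixed-length
  windows are required by the vector definition).
- Representative frame: modal fine label, then the highest-confidence
  frame of that label. Modal-count ties and equal-confidence ties resolve
  toward the lowest frame index — a deterministic, order-stable rule
  chosen because any tie-break is otherwise arbitrary.
- Escalation is strict (`confidence < threshold` consults the human;
  the boundary value stays automatic). The default threshold is 0.5 and
  configurable; note that because the representative frame carries the
  *maximum* confidence among modal frames, escalation rates at moderate
  thresholds are low.
- The 8→3 mapping fixes fear/anger/sadness/disgust → negative,
  happiness → positive, neutral → neutral; surprise → positive and
  contempt → negative are configurable extension defaults (surprise
  accompanies task success in this setting; contempt is valence-negative).
- Video clip k and HR window k are index-aligned from a shared start
  time; an `offset_s` parameter shifts the HR indexing when the streams
  start apart. Output count is `min(#clips, floor(#samples / n))`.

## Haar DWT

The orthonormal convention (1/√2 normalization) is used so that Parseval
energy conservation holds exactly and is testable at 1e-9 on
standardized windows (raw ~100 BPM windows at n=64 have energies ~1e5,
where a 1e-9 absolute bound would sit at float64 round-off). Decomposition
depth defaults to the maximal floor(log2(n)). The feature vector is the
full coefficient concatenation `[A_L, D_L, …, D_1]` rather than sub-band
summary statistics: at n = 2–5 samples per window, summaries would
discard most of the information; a per-band (energy, mean, sd) summary is
available as an option. The concatenated length equals n whenever every
band splits evenly (n a power of two); odd-length bands are repeat-padded
by default (with a strict mode that errors instead), in which case the
vector is slightly longer and reconstruction trims the pad exactly. No
detrending or filtering is applied to HR before the transform by default
(optional per-subject z-scoring exists); the raw stream at these window
lengths is already locally stationary.

## Classification and evaluation

- Stratified shuffled ten-fold CV with a fixed seed; if a training split
  misses a class the partition is re-drawn once, then it errors.
  Temporal adjacency of windows means stratified folds are optimistic for
  intra-subject absolute accuracy; the package reports the comparative
  structure (intra vs inter, scheme vs scheme), which is robust to this.
- Multiclass accuracy is trace/total of the pooled confusion matrix —
  the micro-averaged realization of the binary TP+TN over all formula,
  the only consistent 3-class reading.
- Macro precision/recall use a zero convention for classes never
  predicted or absent; F1 is the harmonic mean of macro precision and
  macro recall.
- Hyperparameters (SVM RBF C=1 gamma=scale; 5-NN Euclidean; 100-tree
  Gini forest) are ordinary defaults; no search is performed.
- Features are z-scored inside the CV pipeline with training-fold
  statistics only, so scaling never leaks test information.

## Problem sizes

Tests and the acceptance script run the generator at its study defaults
(9 subjects, 480–846 s, ≈3000 windows of 2 s at 1 Hz) for the
accuracy-bearing checks; seed-averaged comparisons use 5 seeds.
Reproducibility and orchestration checks use a reduced cohort
(3 subjects, 240–300 s), which exercises identical code paths.

## Known limitations

- With 1 Hz sampling and 2 s windows each feature vector has n = 2
  samples; the DWT is then a single rotation of the raw pair, so
  raw-vs-DWT differences are small by construction at the default
  configuration (they grow with window length or sampling rate).
- The human oracle used in tests returns the modal ground-truth state of
  the clip span — an upper bound on annotator quality.
- Absolute accuracies on synthetic cohorts are not comparable to any
  real-data figure; only orderings and invariances transfer.
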