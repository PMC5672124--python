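# Methods

This note documents the models, parameter choices and numerical decisions
behind `lfpdecode`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic benchmark does and does not
establish.

## The decoding problem

Two bipolar LFP channels (left and right STN or GPi) are recorded at
2000 Hz during a visually cued finger-pressing task. Each trial is one of
three classes — rest, left press, right press — and the decoder must
recover the class from a short window of signal around the behavioural
event. The discriminative physiology is band-limited amplitude modulation:
movement suppresses beta-band (13–32 Hz) amplitude (ERD), elevates gamma
(ERS), and produces a delta-band transient at the motor response, with the
contralateral hemisphere modulating more strongly than the ipsilateral one.

## Synthetic sessions (`synthlfp`)

Real recordings of this kind are not publicly deposited, so the package
generates sessions with known ground truth. Design:

- **Band carriers.** Each of the seven bands is amplitude-modulated
  narrowband Gaussian noise: white noise band-passed (4th-order Butterworth,
  forward–backward) to the band's nominal edges and normalized to unit RMS.
  Narrowband noise rather than sinusoids keeps Hilbert-envelope statistics
  non-degenerate (Rayleigh-like), as in real LFP. Per-band base RMS
  amplitudes fall with frequency (δ 1.0 → high γ 0.2, arbitrary units),
  mimicking the 1/f-like shape of LFP band power.
- **Modulation.** For each movement trial the contralateral channel's band
  carrier is multiplied by a raised-cosine gain profile: 200 ms rise
  starting 150 ms before the motor response, 500 ms plateau at the
  configured gain, 200 ms fall. The ipsilateral modulation depth is the
  contralateral depth divided by the laterality contrast (default 2:1 —
  the literature agrees the contrast exists but does not quantify it, so
  this is a free parameter, not a claim). The delta transient is a
  multiplicative Gaussian bump (σ = 150 ms, default relative amplitude 1.5)
  on the delta carrier at the response time.
- **Background.** Additive 1/f noise (FFT-shaped Gaussian noise with power
  slope −1, RMS 0.5) and 50 Hz line interference (amplitude 0.2, random
  phase per channel).
- **Protocol.** Trial labels are shuffled; cue onsets are spaced by
  uniform [1, 5] s gaps (the validity range for inter-movement intervals);
  motor responses follow the cue by a clipped-normal reaction time
  (0.5 ± 0.08 s). Default trial counts are 58 per class, matching typical
  session sizes for this protocol. All draws flow from one
  `numpy.random.default_rng(seed)`, so identical config + seed is
  bit-identical.

Defaults for the movement-locked gains are low β 0.6, high β 0.7, low γ
1.3, high γ 1.2 — a clearly detectable but not extreme effect; benchmark
runs that stress the decoder use β gain 0.4 ("strong ERD").

**What the generator does not emulate:** tremor and other disease-specific
rhythms, medication state, stimulation artifacts, electrode drift,
non-stationary background power, EMG cross-talk, trial-to-trial latency
jitter beyond the reaction-time draw, and amplitude non-Gaussianity.
Passing tests on this benchmark therefore demonstrate that the pipeline
recovers the class structure its feature set targets — not that any given
accuracy level transfers to patient data.

## Preprocessing (`preprocess`)

Zero-phase (forward–backward) type-I Chebyshev low-pass at 90 Hz, a 50 Hz
IIR notch (Q = 30), then polyphase rational resampling to 256 Hz
(32/250 for 2000 Hz input). Numerical choices:

- The Chebyshev order and ripple are not dictated by the published
  settings, which specify only family and cutoff. The package uses order 7
  with 0.05 dB ripple: after forward–backward application this keeps every
  passband tone within 1 % of its amplitude (odd order also leaves DC gain
  exactly 1) while attenuating 120 Hz by more than 40 dB. The conventional
  0.5 dB ripple would cost up to ~11 % passband amplitude after two passes.
- The notch bandwidth (Q = 30 → ≈1.7 Hz) is a choice; the 50 Hz component
  itself is attenuated far below 10 %, while 40 and 60 Hz pass within 5 %.
- Output length is round(n·256/fs); an event at t seconds indexes sample
  round(t·256) after the full chain (verified by a band-limited-pulse test).

## Band features (`bandfeat`)

- **WPT.** Level-5 wavelet packet transform at 256 Hz gives 32 terminal
  nodes of 4 Hz, frequency-ordered (sequency/Gray-code reordering of the
  natural tree). Bands snap to node edges: δ [0,4), θ [4,8), α [8,12),
  low β [12,20), high β [20,32), low γ [32,60), high γ [60,92). The
  12–13 Hz sliver is indivisible at 4 Hz resolution and is assigned to low
  beta (keeping the analysis-critical beta range intact, at the cost of one
  extra Hz taken from alpha's nominal edge); high gamma runs to 92 Hz
  because 90 Hz is interior to node [88,92). Nodes [92,128) are discarded
  from features but available as a residual for reconstruction checks.
- **Meyer filter.** The discrete Meyer wavelet is realized as a 160-tap FIR
  truncation of the ideal Meyer conjugate-mirror filter (dense-grid FFT
  inversion of H(ω) = √2·φ̂(2ω) with the standard C³ auxiliary polynomial).
  At this length the level-5 analysis/synthesis round trip reconstructs to
  ~2.5·10⁻⁷ relative error; commonly used shorter truncations reconstruct
  only to 10⁻⁵–10⁻² and would dominate the band-signal error budget.
- **Band localization caveat.** Each half-band Meyer filter has a wide
  transition region (fs′/6 to fs′/3 per stage), so tones within roughly
  ±10 Hz of 64 Hz (= fs/4, the first cascade split) leak partially into the
  mirrored node (e.g. a 70 Hz tone places ~11 % of its energy at 56–60 Hz).
  This is intrinsic to realizable wavelet packet trees, not a defect of the
  implementation; tones away from that transition localize ≥ 99 % in the
  correct band.
- **Envelopes.** Hilbert envelopes are computed over the whole recording
  per band, then epochs are cut from the envelope series — this keeps the
  analytic-signal edge artifacts at the recording boundaries instead of at
  every epoch edge.
- **Windows.** Movement epochs span ±2 s around the motor response with
  five contiguous 100 ms feature windows covering −150…+350 ms; rest epochs
  span ±1 s around the cue with windows covering −750…−250 ms. At 256 Hz a
  100 ms window holds 25.6 samples; windows are half-open sample ranges
  [round(t_lo·256), round(t_hi·256)), i.e. 25 or 26 samples — fixed and
  deterministic. A window-sweep utility reproduces the exploratory
  variation of window centers; the shipped default is the final choice
  above.
- **Exclusion rule.** A trial whose cue-onset gap to either neighboring
  trial falls outside [1, 5] s is flagged excluded and skipped by the
  feature pipeline (with a count), mirroring the validity range used at
  acquisition.

## Base classifiers (`baseclf`)

All three consume z-scored features (statistics from the training fold;
distance-based models need commensurate scales).

- **FBANN** — one hidden layer of 10 logistic units and a single logistic
  output, trained by full-batch steepest descent on the MSE (default rate
  0.5, 500 epochs; optional early stopping on a validation split with
  patience 25). Weights initialize at N(0, 1/√fan-in) from the seed. The
  forward pass is checked against an independent scalar-loop evaluation of
  the defining equation to 10⁻¹².
- **RBFNN** — 20 Gaussian centers from k-means (fixed seed), one shared
  width = median inter-center distance, linear output layer solved by ridge
  least squares (λ = 10⁻⁶) — the closed-form global minimum of the output
  layer — with the score clipped to [0, 1].
- **PNN** — Parzen-window class densities with an isotropic Gaussian kernel
  (log-sum-exp stabilized); posterior ∝ prior × mean kernel; decision by
  argmax (exact ties resolve to the first class in canonical order and are
  logged). The smoothing parameter is grid-searched
  ({0.05…2}× median pairwise distance) by inner 3-fold CV accuracy.
  When the training set contains bootstrap-augmented samples the PNN is
  fitted on the original trials only, with the class rebalancing expressed
  through its Bayes priors: interpolated samples shrink the apparent class
  variance of a kernel density estimate and, being near-duplicates, leak
  across inner CV folds and drive the bandwidth search degenerate. Priors
  are the natural rebalancing mechanism of a probabilistic classifier; the
  other two bases train on the augmented set.

Architecture sizes are package defaults (they are not dictated by the
decoding problem): modest capacity appropriate to ~10² trials of 70
features.

## Fusion and two-stage decoding (`ensemble`)

Scores ≥ 0.5 vote 1 (movement / left), otherwise 0 (rest / right); the
three votes fuse by majority — with three voters and two classes no tie is
possible. Decoding is a literal state machine: stage 1 (movement = 1 vs
rest = 0) gates stage 2 (left = 1 vs right = 0), and stage 2 is never
evaluated for rest decisions. Stage 1 trains on movement-window features
(movement class) against rest-window features (rest class); stage 2 trains
only on movement trials. A raw ensemble score, when needed, is the mean of
the three votes (0, ⅓, ⅔, 1).

## Resampling and evaluation (`resampling`, `metrics`, `experiment`)

- **Bootstrap.** Synthetic minority-class samples are convex combinations
  of a uniformly chosen seed point and its r = 5 Euclidean nearest
  neighbors; weights wᵢ = cᵢ/Σc with cᵢ = |N(0,1)| clipped to [0, r]
  (redrawn if all zero), the seed point carrying its own weight c₀. Every
  sample therefore lies in the convex hull of its neighborhood. The
  Gaussian's mean/variance and the folding are package choices — an
  unbounded Gaussian cannot satisfy r ≥ c_d ≥ 0 as stated, and folding
  preserves non-negativity with minimal distortion.
- **Cross-validation.** Stratified 10-fold splitting (stratification is a
  package choice: with ~56-trial minima and unbalanced classes,
  unstratified folds can lose a class entirely). Balancing happens inside
  each training fold after the split; test folds contain only original
  trials, so no synthetic sample can leak into evaluation. The CV error is
  the mean squared difference between desired and realized outputs (mean
  over the N samples).
- **Metrics.** All binary statistics derive from the TP/FP/TN/FN table.
  F-measure is the standard harmonic mean; gmean1 = √(TPR·precision),
  gmean2 = √(TPR·TNR); desirability is the product of mean/std ratios over
  {precision, sensitivity, specificity} (D1) and {gmean1, gmean2,
  F-measure} (D2), composited as (D1·D2)^(1/6) — the geometric mean of the
  six ratios. AUC uses the closed single-threshold form (TPR+TNR)/2, so
  BACC = 100·AUC identically (asserted). Cohen's κ comes with the
  large-sample null standard error
  √(p_e + p_e² − Σᵢ p_{i+} p_{+i}(p_{i+}+p_{+i})) / ((1−p_e)√N)
  using proportion marginals, and the above-chance flag is CI-lower > 0.
  A metric with a zero denominator raises an explicit undefined-metric
  signal with a reason code — it is never silently reported as 0 — and
  reports store it as null with the reason.
- **Pooling.** Fold confusion tables are summed (micro) for the headline
  report; per-fold reports are kept for macro summaries. The stage-2
  report is computed over all true-movement test trials from the stage-2
  classifier's own output, so its metrics are not confounded by stage-1
  errors; the three-class confusion uses the literal two-stage composition.

## Problem sizes

The shipped benchmark configurations are 100 trials per class for the
strong-ERD decoding run and 40 per class for the null-signal control —
large enough for stable fold statistics while keeping a full run in tens of
seconds on one core. The simulator itself scales linearly in session
duration.

## Known limitations

- EDF export is not provided; sessions travel as plain CSV + key=value
  sidecars.
- The WPT band edges are dyadic approximations of the nominal band limits
  (13 → 12 Hz, 90 → 92 Hz); analyses that need exact nominal edges should
  use a direct band-pass instead.
- FBANN training is plain steepest descent by design; it is the slowest and
  least stable of the three bases on near-separable data and benefits most
  from the fused vote.
- The desirability statistic is scale-free but undefined for constant
  metric vectors (zero spread); it is reported as undefined in that case.
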