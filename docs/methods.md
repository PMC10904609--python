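# Methods

This note documents the models, algorithms, and numerical choices behind
`hemonet`, and what the synthetic-data experiments do and do not show.

## Problem setting

The package decodes which finger a participant tapped from functional
near-infrared spectroscopy (fNIRS) recordings over motor cortex. A
continuous-wave instrument measures detected light intensity at two
wavelengths (760 and 850 nm) for each source–detector channel at
3.9063 Hz. Neural activity drives a hemodynamic response: oxygenated
hemoglobin (HbO) rises and deoxygenated hemoglobin (HbR) falls over
seconds. The decoding task is five-class classification (thumb … little)
from single-channel event-averaged concentration time courses.

## Experimental paradigm

The default block design is: 30 s baseline rest, then three sessions each
presenting all five finger conditions as trials of 10 s rest followed by
10 s tapping, then 20 s terminal rest — 350 s in total. The stated parts of
the protocol (30 s baseline, 15 trials of 20 s) sum to 330 s; the 20 s
terminal rest is this package's reconstruction of the remaining time, chosen
so the default paradigm reproduces the documented total.

Condition order within a session is the canonical thumb→little by default;
`build_paradigm(shuffle_seed=...)` randomises it per session. The experiment
helpers shuffle by default because a fixed order confounds condition with
trial position (filter edge effects, the first trial's baseline, carry-over
from the previous trial), which is exactly what randomised designs exist to
break.

## Synthetic-data generator

Real recordings for this task are not publicly deposited, so the generator
is a first-class, tested component that emulates the acquisition:

- **Clean signal.** Each task block contributes a boxcar convolved with a
  canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1,
  undershoot ratio 1/6; peak-normalised per block length), scaled by a
  class- and channel-specific HbO amplitude. HbR is a fixed negative
  multiple of HbO (default −1/3, a typical empirical ratio).
- **Class coding.** By default every channel carries the class signal at
  the same strength, with evenly spaced peak amplitudes
  thumb…little = 0.3, 0.625, 0.95, 1.275, 1.6 µM. This makes the class
  identifiable from a single channel's event average — necessary because
  each (channel, chromophore) average is an independent training example
  and channel identity is not a feature. A `somatotopic_amplitude_map`
  (Gaussian spatial profiles per finger) is available for spatial analyses
  but is not the default, because with pooled single-channel examples it
  makes classes fundamentally confusable. The even spacing means no pair of
  adjacent classes is disproportionately hard. The HbR rows are
  sign-mirrored, scaled copies; a linear softmax over one latent amplitude
  direction can only carve contiguous intervals and therefore cannot
  separate a class whose positive (HbO/HbT) and negative (HbR) clusters
  interleave with other classes' — a structural reason the multinomial
  logistic baseline saturates near 60 % while nonlinear models can approach
  the noise ceiling, mirroring the qualitative gap between model families
  on real data.
- **Forward optics.** Concentrations map to optical densities by the
  Beer–Lambert relation (3 cm separation, DPF 6.0, tabulated extinction
  coefficients in 1/(µM·cm)) and to intensity as `I = I0·10^(−ΔOD)`, so the
  preprocessing inverse recovers the injected signal exactly on noiseless
  data.
- **Noise.** Additive, at the intensity level (baseline 1.0): cardiac
  (1 Hz), respiratory (0.3 Hz) and Mayer-wave (0.1 Hz) sinusoids with
  per-channel random phases, plus white measurement noise. The respiratory
  and Mayer components lie inside the 0.01–0.5 Hz analysis band and are the
  dominant nuisance after filtering. The cardiac component lies below the
  1.95 Hz Nyquist frequency; no anti-alias constraint is imposed, matching
  a real instrument.
- **Artifacts.** Optional isolated single-sample spikes and sustained
  baseline steps, Poisson-placed at configured per-minute rates, with all
  positions logged as ground truth.
- **Presets** (study conditions, fixed once from a forward SNR
  calculation — matched-filter amplitude spread of event-average rows
  against the class-level gaps — and not revisited):
  - `default`: cardiac 0.01, respiration 0.005, Mayer 0.005, white 0.005;
  - `high_snr`: cardiac 0.005, respiration 0.0005, Mayer 0.0002,
    white 0.0003 (worst class-boundary z ≈ 3.4 for HbO rows, ≈ 2.0 for
    HbR rows: cleanly decodable);
  - `mid_snr`: cardiac 0.01, respiration 0.005, Mayer 0.002, white 0.006
    (worst z ≈ 1.1 / 0.45: partially confusable);
  - `null`: all class amplitudes equal (0.8 µM) under default noise —
    nothing to decode.

What the generator does **not** emulate: photon transport and partial-volume
effects, subject anatomy and optode-coupling variability, 1/f physiological
background, task-correlated motion, inter-subject amplitude differences.
Passing tests therefore show that the pipeline and classifiers behave
correctly under the stated signal model, not that the real-data accuracies
are reproduced.

## Preprocessing pipeline

Fixed stage order: truncation → spike removal → channel rejection → optical
density → Beer–Lambert inversion → band-pass → motion correction →
normalisation.

- **Truncation** keeps [first onset − 5 s, last offset + 5 s]; the 5 s pad
  preserves the epoch pre-onset margin. A `time_offset` keeps absolute
  stimulus times valid after cropping.
- **Spike removal** replaces samples whose robust z-score
  (|x − median| / (1.4826·MAD)) exceeds 5 with linear interpolation between
  valid neighbours. The detector and threshold are this package's choices
  (the protocol only names "interpolation"); the threshold is conservative
  and calibrated by seeded-artifact tests.
- **Channel rejection** drops channels whose intensity coefficient of
  variation (population sd / |mean|, per wavelength) strictly exceeds
  7.5 %; a channel exactly at the threshold is retained, making the
  boundary deterministic.
- **Optical density** is −log10(I/Ī) with Ī the temporal mean, so recovered
  concentrations are relative to the recording mean (a per-channel constant
  offset, irrelevant after filtering).
- **MBLL** solves the 2×2 extinction system per sample. Extinction
  coefficients are a compiled standard tabulation (760 nm: HbO 586,
  HbR 1548.52; 850 nm: HbO 1058, HbR 691.32, in cm⁻¹/(mol/L), converted to
  1/(µM·cm)); DPF 6.0 at both wavelengths. Singular systems
  (rank-deficient extinction matrix) are rejected.
- **Band-pass**: zero-phase (forward–backward) Butterworth, order 4, band
  0.01–0.5 Hz. The protocol description swaps the low/high-pass labels; a
  band-pass with these edges is the only physically sensible reading
  (removes drift and cardiac pulsation, keeps the HRF).
- **Motion correction (TDDR)** re-weights the temporal derivative of the
  sub-0.5 Hz component with an iteratively re-weighted Tukey biweight
  (tuning 4.685, iterated until the robust mean is stable to √machine-eps
  relative), removes the deviation from the robust fit together with the
  residual net drift, and re-integrates; content above 0.5 Hz passes
  through. Net linear drift is treated as motion artifact — by construction
  the corrected series is drift-free. The implementation is verified
  bit-identical to an independent implementation of the published
  algorithm on identical inputs. Two properties matter for interpretation:
  (1) transparency on artifact-free data holds in the noise-dominated
  regime (weak responses relative to in-band noise, as in real single-trial
  fNIRS); strongly signal-dominated sub-0.5 Hz content is shrunk by the
  biweight (both implementations, 10–30 %), so the transparency figure is
  measured on low-amplitude (0.2×) recordings; (2) isolated single-sample
  spikes at 3.9 Hz are *not* corrected by TDDR (the 0.5 Hz split smears
  them and re-integration can worsen them) — they are removed upstream by
  the interpolation stage; TDDR targets sustained baseline shifts.
- **Normalisation**: per channel and chromophore, z-score plus an additive
  offset of 10 ("baseline value 10" read as the offset of the standardized
  trace). Applied independently per chromophore, it intentionally breaks
  the HbT = HbO + HbR identity, which holds exactly up to this stage.

## Features

Each task event yields one epoch per (channel, chromophore) from 5 s before
onset to 15 s after. At 3.9063 Hz the window is represented by exactly 77
samples, the feature dimensionality used throughout; the epoch starts at
sample ⌈−5·fs⌉ relative to the onset sample (20 s × 3.9063 Hz = 78.125, and
the fixed 77 keeps the window strictly inside the (−5 s, 15 s) interval).
Within-condition epochs are averaged per channel and chromophore; each
average is one labelled example, so a run contributes
channels × chromophores × conditions rows. HbT rows are included by default
and switchable. Feature scaling is column-wise standardisation with
statistics learned on the training split only.

## Classifiers

Ten models under one scikit-learn fit/predict contract, with
`predict_proba` rows summing to one:

- **LDA** — scatter matrices S_W (within) and S_B (between) and the
  eigenpairs of S_W⁻¹S_B are computed directly and exposed as fitted
  attributes; classification is the standard linear discriminant (the
  sklearn solver stands behind the surface). Grid: solver
  {svd, lsqr, eigen} × shrinkage {none, auto}, excluding the undefined
  svd+auto cell.
- **QDA** — per-class Gaussian densities with covariance shrinkage
  reg_param ∈ {0, 0.1, 0.5, 1.0}, posteriors by Bayes' rule.
- **MNLR** — multinomial logistic regression in the reference-class
  parameterisation (K−1 weight vectors, last class as reference),
  implemented in-package and optimised with L-BFGS-B; the L1 penalty uses
  the split w = u − v, u,v ≥ 0 reformulation. Grid: penalty {l1, l2} ×
  C ∈ {0.01, 0.1, 1, 10, 20}; intercepts unpenalised.
- **Random forest** and **XGBoost** with the protocol grids
  (n_estimators {50,100}; max_depth {None,5,10}; RF min_samples_split
  {2,5}, min_samples_leaf {1,4}; XGBoost learning rate {0.1,0.01,0.001});
  max_depth None maps to XGBoost's depth-0 "no limit" under the histogram
  tree method. Grid search is exhaustive, stratified 5-fold, accuracy-
  scored, ties broken first-in-grid.
- **Deep models** on the package's NumPy autodiff engine (reverse-mode,
  gradient-checked against numerical differentiation): a dense baseline
  (1024/512/128/64 + output, batch-norm + ReLU), a two-layer LSTM(50)
  stack, a three-layer bidirectional LSTM (50/50/20), a parallel CNN
  (convs 64/64/32, kernels 3/5/3, leaky ReLU) + LSTM (64/64/32) hybrid, and
  **Hemo-Net**: three inception blocks (1×1 bottleneck; parallel bias-free
  convolutions with kernel lengths 10/20/40; a stride-1 max-pool path with
  its own bottleneck; concatenation, batch-norm, ReLU; "same" padding
  throughout so the 77-sample length is preserved), a residual connection
  from the input across the block stack through a linear projection with
  batch-norm, global average pooling over time, and a dense softmax
  classifier. Default width 32 filters / bottleneck 32 per block
  (inception-time convention; the protocol does not state widths).
- **LSTM cell.** The canonical update (c_t = u∗g + f∗c_{t−1},
  a_t = o∗tanh c_t) is the default. A printed variant that additionally
  wraps the cell update and output in sigmoids is implemented behind
  `literal=True` in `lstm_step` / `literal_cell=True` in the LSTM
  classifier; it is almost surely a typographical artefact of the source
  description, but both behaviours are available and tested.

**Training plan.** Batch size 32, L2 kernel penalty (1e-4), Adam, and
either a triangular cyclic learning rate in [1e-5, 1e-2] (baseline DNN,
Hemo-Net; 8-epoch triangle) or a fixed 1e-4 rate (recurrent/hybrid). Early
stopping on a 10 % validation split with patience 20 (max 500 epochs) by
default; best-validation weights and batch-norm statistics are restored.
Optimiser identity, cycle period, and stopping are this package's choices —
the protocol states only batch size, penalty, and learning-rate policy.
Training is deterministic given the seed.

## Evaluation

Accuracy is the indicator mean Σ I(y_pred = y_true)/N. Per-class precision
Tp/(Tp+Fp), recall Tp/(Tp+Fn), and F1 (harmonic mean) are derived from the
K×K confusion matrix, with macro (unweighted) and support-weighted
averages. Zero denominators yield 0 and set an explicit flag (degenerate
synthetic runs only). Splits are stratified-pooled (default, 80/20) or
by-run (whole runs held out).

**Split-choice rationale.** Rows derived from the same run share trials:
dHbT rows are near-duplicates of dHbO rows, and the MBLL inversion
correlates noise across chromophores. Under a pooled split, memorising
models recognise these twins across the train/test boundary (measured on
null-effect data: 0.31–0.43 "accuracy" pooled vs 0.19–0.23 with whole runs
held out). The chance-level and model-ordering experiments therefore hold
out whole runs and shuffle condition order per session; the high-SNR
recovery experiment uses the default pooled split, where the genuine signal
dominates.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at deliberately scaled sizes: montages of
12–16 channels, 4–12 runs per experiment, a width-reduced Hemo-Net
(8 filters / bottleneck 8), and 1–15 training epochs depending on the
check (chance-level checks need no convergence; recovery checks train to
high accuracy). The chance-level experiment uses ≥ 500 held-out rows; the
ordering experiment takes the median over 5 seeds. Chance on null data and
≥ 0.9 recovery at high SNR are stable across seeds at these sizes. In the
mid-SNR ordering, the MNLR gap is large and stable (the structural ceiling
described above), while Hemo-Net and the random forest are closely matched
near the noise ceiling: the median ordering Hemo-Net ≥ RF holds at the
stated seeds, but single-seed medians can put the forest a fraction of a
point ahead.

## Known limitations

- The generator's additive-sinusoid noise model is simpler than real
  physiological background; its class-amplitude coding is deliberately
  identifiable, so absolute accuracies on synthetic data say nothing about
  real-data accuracy.
- TDDR's transparency is regime-dependent (see above); on strongly
  signal-dominated traces the biweight shrinks genuine slow structure.
- The MNLR ceiling on synthetic data is a property of the generator's
  one-dimensional amplitude coding, not a general statement about
  multinomial regression.
- The deep models run on a NumPy engine tuned for clarity and testability;
  it is single-threaded and not performance-competitive with GPU
  frameworks, which is why tests use width-reduced networks.
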