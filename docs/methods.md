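# Methods

## Pipeline overview

The classifier decodes two-class motor imagery from epoched EEG
(trials × channels × samples, microvolts) in five stages:

1. **Preprocessing.** Fifth-order Butterworth band-pass 8–30 Hz applied
   forward and backward (zero phase, odd-reflection padding of
   3·max(len(a), len(b)) samples). When a continuous recording and an
   event table are supplied, the recording is filtered before epochs are
   cut (half-open, 0-based windows `[onset + start·fs, onset + end·fs)`,
   default 0.5–3.5 s after the cue), keeping filter transients out of the
   analysis windows. Already-epoched data are filtered per trial; the
   trial edges then carry small transients, which is why assertions about
   filter behavior in the tests discard ~0.5 s margins.
2. **Feature extraction** in four domains (details below).
3. **Per-domain selection.** RFE with a 100-tree random forest: refit,
   drop the single feature with the smallest mean impurity decrease
   (ties → lowest column index), repeat until Na features remain.
4. **Local rotation + composite fusion.** Random partition of the Na
   columns into K subspaces, per-subspace PCA on a 75% class-stratified
   trial subsample (without replacement), all components kept, component
   signs fixed by making the largest-magnitude loading positive; the
   block-diagonal, column-reordered matrix R″ is orthogonal and
   `F_rotated = F_rfe · R″`. Composite set: `[F_rotated, F_rfe]`.
5. **Stacking.** Per-domain base classifier on the composite set
   (random forest default; RBF/linear SVM with standardization and 3-fold
   sigmoid probability calibration as alternatives). Meta-classifier: a
   one-hidden-layer (100-unit, rectifier, adaptive first-order optimizer,
   ≤200 epochs) perceptron over the four out-of-fold probability blocks
   plus the C−1 LDA coordinates of the concatenated significant features,
   with input standardization. Prediction takes the arg-max class
   (ties → lower class index).

## Feature domains

- **Time:** per channel mean, population variance (divide by T), RMS, and
  Higuchi's fractal dimension. The fractal dimension averages normalized
  curve lengths `L_m(l)` over the l offsets at each time interval
  l = 1..l_max (default 10) and fits ln ⟨L(l)⟩ against ln(1/l) by least
  squares; the printed single-interval ratio form of the estimator is
  dimensionally a slope, so the standard slope fit is implemented. A
  constant signal has zero curve length and returns 1.0 with a warning
  (a constant is a degenerate line).
- **Frequency:** unnormalized forward DFT; band features sum |X(k)|² over
  positive-frequency bins with frequency in the half-open band
  [low, high); PSD divides by T. No one-sided doubling is applied; the
  Parseval identity used in the tests (`Σ_k |X(k)|² = T Σ_t x(t)²`)
  matches this convention. Default bands: alpha 8–13 Hz, beta 13–30 Hz
  (configurable; the literature has no single canonical edge).
- **Time-frequency:** db4, 4-level DWT with periodic signal extension so
  orthogonal energy conservation holds exactly (for signal lengths
  divisible by 2^levels; other lengths are padded internally and conserve
  energy only approximately); detail energies at the
  levels mapped to the rhythms. The default map D4→alpha, D3→beta follows
  the source method's convention even though the nominal dyadic bands at
  100 Hz put D3 at 6.25–12.5 Hz (covering most of the mu band) and D4 at
  3.125–6.25 Hz; `level_map` lets users adopt the nominal mapping, and
  the tests assert tone placement by the dyadic ranges (a 10 Hz tone
  lands in D3, a 5 Hz tone in D4). Inputs at other sampling rates are
  resampled to 100 Hz first so levels keep their frequency meaning.
- **Spatial:** filter-bank CSP, six 4-Hz bands from 8 to 32 Hz, each
  band-passed independently from the broadband epochs. Per-trial
  covariances are trace-normalized; the composite covariance is
  eigendecomposed (descending, stable sort so ties keep original order)
  and regularized by ε = 1e-10·trace/Nch only if numerically singular;
  m = 2 filter pairs are retained per band (24 spatial features at the
  default bank), and the log-variance-share denominator runs over the 2m
  retained rows.

## Stacking choices

Meta-training probabilities are produced **out-of-fold** (stratified
5-fold internally, bases refit on all training data afterwards). Training
the meta-classifier on in-sample base probabilities would leak labels
through overfitted bases; out-of-fold blocks are the standard remedy in
stacked generalization, and the choice matters: with in-sample
probabilities the meta-learner mostly learns that the bases are
near-perfect on training data.

The LDA supplement always uses the eigen solver with Ledoit–Wolf
shrinkage of the within-class scatter. Concatenated significant features
(4·Na columns) can exceed the trial count inside a training fold, where
plain LDA is undefined; automatic shrinkage handles that continuously and
reduces toward plain LDA when the scatter is well-conditioned.

Contribution rates: for meta input i,
`importance_i = Σ_h |W_in[i,h]| · Σ_o |W_out[h,o]|`; a domain's rate sums
its C probability inputs, normalized to 100% over the four domains. The
LDA inputs are excluded from that normalization and reported as their
share of the total weight mass, so the domain comparison is not diluted
by the supplement.

## Synthetic data

`generate_mi_eeg` emulates the ERD/ERS phenomenology: each trial is a sum
of alpha (8–12 Hz) and beta (16–24 Hz) oscillations — narrow-band
filtered Gaussian noise normalized to unit RMS, not pure tones, so
spectral, wavelet and fractal features are non-degenerate — plus a 1/f
(power slope −1) background and white noise. For a trial of class c, the
oscillation amplitude on channels `erd_channels[c]` is scaled by
(1 − erd_depth) (band power by its square) and on the other class's
channels by (1 + ers_gain). Defaults: 100 trials/class, 8 channels,
100 Hz, 3 s, depth 0.6, gain 0.2, amplitudes alpha 1.0 / beta 0.7 / pink
0.6 / white 0.4 — a strongly separable regime analogous to a good BCI
subject. `domain_signal_toggles` switches independent mechanisms
(lateralized ERD/ERS; global alpha or beta power shifts; broadband
noise-variance shift) for tests that need signal visible to specific
domains; the feature-level generator (`generate_feature_tables`, Gaussian
blocks with planted mean shifts) isolates selection/rotation/stacking
from the signal-processing front end entirely.

What passing on this benchmark does **not** show: robustness to real EEG
nuisances — artifacts (EOG/EMG), non-stationarity across a session,
volume-conducted correlated noise, electrode drift, subject variability.
The generator's channels are independent given the class, which makes
spatial filtering easier than on real recordings; absolute accuracies
here do not transfer to competition data.

## Evaluation protocol

Stratified 5 × 5-fold cross-validation (4:1 split; stratification keeps
class balance in every fold — the protocol source does not say whether
its folds were stratified, and balanced data make the difference small).
Every supervised stage (CSP, RFE, rotation, LDA, bases, meta) is refit
inside each training fold. Metrics are computed from binary confusion
counts with the numerically larger label as positive; precision, recall
and F1 are defined as 0 (with a warning) when their denominator is 0.
A label-permutation probe (default 10 permutations) verifies the
protocol leaks no labels: mean permuted accuracy must sit at chance.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| band | 8–30 Hz | preprocessing band-pass (sensorimotor rhythms) |
| filter_order | 5 | Butterworth order before the forward-backward pass |
| epoch_window | 0.5–3.5 s | analysis window after the cue |
| l_max | 10 | Higuchi maximum time interval |
| filterbank | 8–32 Hz, 4-Hz steps | CSP sub-bands |
| csp_m | 2 | CSP filter pairs per band |
| na | "auto" | RFE target; auto = smallest domain width |
| K | 7 | rotation subspaces |
| resample_fraction | 0.75 | trial subsample for per-block PCA |
| base_kind | random_forest | first-layer classifier |
| oof_folds | 5 | internal stratified folds for meta-training probabilities |
| cv | 5 × 5 | evaluation protocol |

When Na is not divisible by K, the remainder r features go one-per-block
to the first r blocks. All randomness flows from one seed through named
per-stage seed derivations (CRC-mixed `SeedSequence`), so a run is
reproducible from its config snapshot.

## Problem sizes used in tests and the acceptance script

Synthetic study conditions: 100 trials/class, 8 channels, 100 Hz, ERD
depth 0.6; pipeline Na = 16 (the smallest domain width at 8 channels, so
all four domains reach the same Na) and K = 7. End-to-end checks use
5-fold CV over 5–10 generator seeds; the acceptance script uses 3 seeds
for CV accuracy and fusion trends and 5 label permutations. Structural
identities run over 50 random rotation configurations and 10 random
covariance draws; recovery rates over 20 seeds. Unit tests use smaller
forests/trial counts where the property under test does not depend on
ensemble size.

## Known limitations

- Binary classification only (the CSP construction is two-class; the
  stacking layer itself is C-class ready).
- Rotation Forest the *classifier* is out of scope; only the feature-space
  rotation is implemented.
- No artifact rejection beyond band-pass filtering; EDF is the only
  supported container for continuous input.
- The D4→alpha default mapping is a faithful reproduction of the source
  convention, not of the dyadic frequency split; users decoding at other
  sampling rates should check `level_map` against their band layout.
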