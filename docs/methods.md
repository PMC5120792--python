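# Methods

`emasynth` implements a real-time-capable articulatory speech synthesizer:
articulator positions captured by electromagnetic articulography (EMA) are
mapped to acoustic parameters by a feed-forward DNN and rendered to audio by
a mel-log-spectrum-approximation (MLSA) vocoder. A linear cross-speaker
calibration lets a new speaker (or a new session) drive a synthesizer built
from a reference speaker's data. This note documents the model, the numeric
choices, and what the synthetic test bench does and does not show.

## Source-filter vocoder

Each 512-sample analysis frame (Blackman window, hop 220 samples at
22,050 Hz, i.e. a nominal 10 ms / 100 Hz frame rate) is described by 25
mel-cepstral coefficients c_alpha(m), m = 0..24, defining the vocal-tract
filter

    H(z) = exp( sum_m c_alpha(m) * ztilde^-m ),
    ztilde^-1 = (z^-1 - alpha) / (1 - alpha z^-1),

with warp coefficient alpha = 0.455, which approximates the mel scale at
this sample rate. c_alpha(0) is the log gain; the remaining coefficients are
gain-free spectral envelope shape.

**Analysis.** Coefficients minimize the standard mel-cepstral
spectral-matching criterion mean[exp(R) - R - 1] with
R = log I - log |H|^2 over the FFT grid, where I is the Blackman
periodogram. The solver is a damped Newton iteration (analytic gradient and
Hessian in the cosine basis on the warped frequency grid), warm-started from
a weighted least-squares fit of the log spectrum; at most 30 iterations,
stopping when the criterion improves by less than 1e-6. The periodogram is
floored 80 dB below its per-frame maximum: deep harmonic nulls otherwise
drive coefficients outside the stable range of the synthesis filter's Padé
approximation. The criterion is exactly gain-equivariant: scaling audio by k
shifts c_alpha(0) by ln k and nothing else.

**Synthesis.** The exponential transfer function is realized as
exp(b0) * exp(F1) * exp(F2) after the standard linear recoding b(M) = c(M),
b(m) = c(m) - alpha*b(m+1), where F1 collects the first-order term and F2
the rest. Each exp(F) is approximated by an order-5 Padé rational
R(F) = N(F)/N(-F) in a per-sample feedback structure. Because
R(-F) = 1/R(F) identically, inverse filtering (residual extraction) with
negated coefficients is the exact algebraic inverse of synthesis; the
analysis-synthesis round trip on a synthetic vowel re-measures at
~1e-13 dB mel-cepstral distortion, and the filter's impulse-response
spectrum matches the analytic warped log spectrum to < 0.01 dB over
0-8 kHz for realistic coefficient magnitudes. Filter coefficients are
linearly interpolated per sample from the previous frame's values to the
current frame's (causal; the cold start holds the first frame).

**Excitation.** Two sources are provided: (i) pitch-driven — a pulse train
by phase accumulation on voiced frames (pulse amplitude sqrt(period), so the
excitation has unit average power) and unit-variance white noise on unvoiced
frames; (ii) fixed-template — one glottal period (extracted from a sustained
vowel by inverse filtering, or any supplied single-period waveform) tiled
end-to-end, producing the constant-pitch "robotic" voice used when no
glottal activity exists (silent speech). Pitch is tracked by frame-wise
autocorrelation: a frame is voiced when the normalized peak in the 50-400 Hz
lag range exceeds 0.3 and frame RMS exceeds 2% of the loudest frame; the
peak lag is refined parabolically.

## Articulatory processing

Nine 3-D sensor trajectories (tongue tip/dorsum/back, upper/lower lip, two
lip corners, jaw, velum) plus a 6-DOF reference coil are processed as:

1. **Head correction** — each sensor is expressed in the reference coil's
   rigid frame, p' = R^T (p - t) per frame.
2. **Down-sampling** 400 -> 100 Hz with an order-8 Butterworth zero-phase
   anti-alias filter (maximally flat passband: constants and slow
   articulatory movements are amplitude-true, which a rippled Chebyshev
   design is not), then decimation.
3. **Parameterization** — `raw27` (all coordinates); `midsag14` (drop the
   lateral lip-corner sensors, keep x-y of the remaining 7 in the reference
   coil's midsagittal plane, which we take to be its x-y plane);
   `pca10`/`pca7` (principal components of the z-scored raw27 data — scaling
   before rotation keeps millimetre-scale articulators from dominating the
   axes).
4. **Silence removal** using phone segmentations (frames whose center time
   falls in a SILENCE interval), **z-scoring** with statistics fit on
   training frames only, and **causal context stacking** of each frame with
   its 4 predecessors (50 ms); the first frames replicate frame 0 so the
   frame count is preserved without lookahead.

## Articulatory-to-acoustic DNN

A fully connected net, input 5d -> 200 -> 200 -> 200 -> 25 outputs, leaky
rectifier hidden units (negative slope 0.01, configurable), linear output,
weights initialized N(0, (1/N)^2) with N the fan-in, zero biases. The loss
is the frame MSE over the 25 z-scored outputs. Training grows the network
layer by layer: stage k keeps the k-1 trained hidden layers, adds a fresh
hidden layer and a fresh output layer, then fine-tunes all weights. Each
epoch shuffles the training frames into 100 blocks and runs one
Polak-Ribiere conjugate-gradient pass per block, capped at 3 line searches
(quadratic/cubic interpolation, best-seen parameters kept, so a block's loss
never increases). A stage stops when validation MSE has not improved for 20
epochs (best weights restored); items are split 90/5/5 at the item level
(odd leftovers go to validation), so frames from one utterance never
straddle the split.

`max_epochs` defaults to 500 as a safety bound; the bundled experiments use
40 per stage, which the patience rule rarely exhausts at the bench's
noise level.

## Cross-speaker calibration

The new speaker's frames map to the reference articulatory space by a single
affine transform y = A x + b fitted frame-by-frame (no temporal context).
A global integer frame delay (speaker + system latency) is estimated first:
for each candidate in a +/-30 frame grid (+/-300 ms, step 1) the sequences
are shifted and cut per item, an ordinary least-squares model is fitted on
speech frames, and the delay with minimal MSE wins (ties toward the smaller
magnitude). No regularization by default; rank-deficient designs raise an
error naming the dependent columns. Note the fitted map is the *inverse* of
the simulator's generative transform: if x_new = A x_ref + b then the
calibration recovers (A^-1, -A^-1 b), which is what the tests assert.
Calibration quality is reported per sensor as the mean Euclidean distance
(mm) between predicted and reference midsagittal positions over speech
frames.

## Streaming

The closed-loop cascade (calibration -> DNN -> MLSA with the fixed-template
excitation) runs frame-by-frame: each incoming articulatory frame yields
exactly one hop (220 samples) of audio. The streaming path and the offline
batch path share every numeric kernel and evaluate the DNN row-wise in both
cases, so their outputs are bit-identical — the real-time property is
verified as causality plus sample-exact stream/batch equivalence plus
constant per-frame state, not as wall-clock latency, which is
hardware-bound.

## Synthetic test bench

The generator emulates a paired articulatory-acoustic recording session with
known ground truth:

- 17 pseudo-phones (10 "vowels", 7 "consonants"), each owning a fixed
  articulatory target drawn once from the seed, uniform in +/-8 mm per
  dimension (d = 14 by default); silence is a rest posture at the origin.
- Items (isolated vowels 0.5 s, VCVs, 6-12-phone pseudo-sentences, mean
  duration about 2 s including 0.2-0.4 s edge silences) follow the
  piecewise-constant target path smoothed by a 50 ms raised-cosine window,
  plus low-pass coloured noise of 0.3 mm sd at 400 Hz; items are then
  decimated to 100 Hz. Defaults give 50 items ~ 10,000 frames.
- The "true" articulatory-to-acoustic relation is a fixed random shallow
  network of 50 tanh basis functions mapping the stacked 5x14 context to 25
  mel coefficients (smooth, Lipschitz-bounded, reproducible); observed mel
  frames add N(0, 0.3^2) noise per coefficient — comparable to the clean
  coefficient spread, a deliberately noisy regime so that reaching the noise
  floor demonstrates genuine function recovery.
- New-speaker sessions apply x_new(t) = A x_ref(t - delay) + b + noise with
  A a +/-15% perturbation of the identity, b ~ N(0, 2 mm), delay 7 frames,
  sensor noise 5% of the articulatory sd.

What this bench does **not** model: real articulator dynamics
(coarticulation, speaker-specific trajectories), phonetically faithful
acoustics, vocal-tract physics, or human perception. Passing tests therefore
demonstrate correctness and recoverability of every algorithmic stage under
known conditions — not that the human intelligibility levels reported for
real EMA data would be reproduced.

## Problem sizes used by the bundled experiments

The study-scale bench trains on a 180-item corpus (~20,000-23,000 speech
frames after silence removal); the calibration session uses 50 pseudo-
sentence items split 40 train / 10 held-out (~7,000 training speech frames
over a +/-30-frame delay grid, per-sensor mm error reported on the held-out
items); and the closed-loop analogue streams 30 vowel stimuli (10 classes x
3 repetitions, 0.9 s each) through the full cascade before nearest-centroid
classification by mel-cepstral distortion on steady-state frames.

## Known limitations

- The mel-cepstral Newton solver assumes the 80 dB dynamic-range floor;
  pathological spectra (pure digital tones) can still produce large
  coefficients that stress the Padé approximation.
- The MLSA inverse is exact for frozen coefficients; with per-sample
  interpolation the forward/inverse composition is exact only to the extent
  both passes see identical coefficient ramps (they do here).
- The pitch tracker is a plain autocorrelation method; it is adequate for
  the bench's sustained sounds, not a production pitch tracker.
- Seriation of confusion matrices is exact only up to 8 categories;
  beyond that a greedy + 2-opt search is used, which is a heuristic.
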