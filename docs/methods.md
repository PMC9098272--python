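# Methods

## The decoding problem

Multiclass motor-imagery EEG decoding: given a cue-locked multichannel trial
(here −0.5 s to 4 s around the cue, microvolts, 250 Hz), predict which of K
movements the subject imagined. The discriminative physiology is event-
related desynchronisation (ERD): imagery suppresses the power of band-limited
sensorimotor rhythms (mu 8–12 Hz, beta 18–26 Hz) over the cortical patch
representing the imagined effector, so class information lives in *which
channel group loses band power after the cue*.

## Synthetic data generator

The generator emulates exactly that physiology and nothing more. Each trial
is a sum of

* **background**: per-channel Gaussian noise with a 1/f^α spectrum (α =
  `background_exponent`, default 1.0 — the canonical EEG-like slope), scaled
  to `noise_sd` µV (default 5);
* **rhythms**: one band-limited oscillation per class (white noise brick-wall
  filtered to that class's band, fixed 10 µV RMS) on that class's channel
  subset. Default topographies are disjoint contiguous channel blocks, one
  per class, mimicking somatotopic lateralisation; default bands alternate
  mu and beta across classes.

In a trial of class k, the class-k oscillation's envelope is multiplied by
`sqrt(1 − erd_depth)` from the cue onward (0.2 s raised-cosine ramp to avoid
a spectral step edge), so its *band power* drops by the factor
`(1 − erd_depth)`. All other rhythms persist unchanged: before the cue every
trial looks statistically identical, and the only class information is which
block desynchronises. `erd_depth` defaults to 0.8 — a deep, clearly decodable
ERD; 0 removes all class information by construction.

Deliberately not modelled: volume conduction (sources mix into all channels
in real EEG; here topographies are disjoint), electrode geometry, inter-
subject and inter-session variability, non-stationary background. Passing
tests on this generator therefore demonstrate that the architecture and the
training protocol can recover spatially localised band-power modulation from
raw samples — not that any particular accuracy transfers to recorded EEG.

A fixed, non-learned ERD detector (post/pre band-power ratio per candidate
class, argmin) serves as a physiology-level oracle: its accuracy must be
chance at `erd_depth = 0` and rise monotonically with depth. Band powers are
measured by Welch averaging (scipy), a deliberately independent route from
the generator's synthesis path. Because the pre-cue baseline is only 0.5 s
(about two independent envelope cycles of a 4 Hz-wide rhythm), per-trial
power ratios are heavy-tailed; validation therefore compares the ratio of
*trial-averaged* powers, which is unbiased for the attenuation factor.

## Windowing conventions

Sample `s` of a trial maps to cue-relative time `t0_offset_s + s / fs`; all
window arithmetic is half-open `[start, start + length)`. Crop starts sweep
the half-open range `[start_min, start_max)` in steps of `stride_samples`,
giving `ceil(range_samples / stride)` windows (one window when the range is
empty). With the defaults — 2 s windows, starts from −0.5 s to 2 s, 250 Hz,
stride 1 — each trial yields exactly 625 crops, the figure the architecture
is quoted with; an inclusive right endpoint would give 626 and is not used.
Start samples are `round((start_min − t0_offset) · fs)` plus multiples of
the stride; with the defaults the rounding is exact.

## Network and numerical choices

* **Length-preserving convolutions.** All temporal convolutions pad to
  preserve length (the published layer table asserts the time axis survives
  block 1 unchanged). Even kernels pad one sample more on the left: 32/31
  for the (1, 64) kernel, 8/7 for (1, 16).
* **Pooling.** Width-3, stride-3 pooling floor-divides the time axis; four
  stages leave `T′ // 81` steps (500 → 166 → 55 → 18 → 6). Blocks 1–3
  max-pool, block 4 mean-pools.
* **No conv bias.** Convolutions are immediately followed by affine
  batch-norm (eps 1e-3, momentum 0.01 on running statistics), which makes a
  bias redundant and keeps the parameter calibration well-posed.
* **Recurrent cell.** Gates are dense on globally mean-pooled inputs/states;
  only the candidate path is convolutional: an odd-width (default 3) 1-D
  kernel slides along the feature axis with symmetric zero padding. This
  length-preserving convolution forces the hidden width to equal the pooled
  feature width (D·F4). The candidate already blends the previous memory
  through the forget/input gates and is carried forward directly as the next
  cell memory.
* **Initialisation.** Recurrent (state-to-state) matrices start orthogonal
  (QR of a Gaussian draw, sign-fixed for determinism); all other weights are
  fan-in-scaled uniform; biases zero. One integer seed fixes initialisation,
  batch order and dropout masks; two runs with the same seed produce
  identical loss series bit for bit.
* **Dropout** 0.25 after every block (0.5 is exposed for cross-subject
  validation settings). **ELU** activations throughout the trunk.
* **Autodiff.** The package ships a small reverse-mode tape on numpy
  (float32) providing exactly the ops the model uses; every backward pass is
  verified against central finite differences in the test suite. Gradients
  of the recurrent loop come from ordinary backpropagation through time on
  the tape.

## Calibration of unprinted hyperparameters

The per-block filter counts F1..F4, the recurrent hidden width and the
attention key width are fixed by the only published anchor: the total of
17,972 trainable parameters for a 22-channel, 4-class, depth-1 model.
`midecoder.calibration` enumerates widening power-of-two ladders
F1 ≤ F2 ≤ F3 ≤ F4 ≤ 64 (hidden width tied to D·F4 by the candidate
convolution) and solves the closed-form parameter count for an integer
attention key width in [4, 64]. Three exact solutions exist; the package
selects the one maximising total trunk filters (capacity in the feature
extractor), tie-breaking on the smaller key width:
**F = (8, 16, 32, 32), hidden 32, key width 26.** The search and the
verification against a freshly built model run in `scripts/calibrate_params.py`
and in the test suite.

## Training protocol

Adam (lr 1e-3, batch 64) minimising window-level cross-entropy; the
alternative `averaged_prob` mode averages window softmax outputs per trial
before the log-loss (both readings of "average prediction loss" are
implemented; per-window is the default, the standard cropped-training
construction). Trials are split 2/1/1 into train/validation/test across four
class-stratified groups rotated so every trial is tested exactly once;
splitting precedes cropping, so windows never straddle a split boundary.
After each epoch the validation *trial* accuracy (mean window probability,
argmax) is recorded; the best-validation weights are restored at the end
(patience 15 by default).

## Desk-scale study sizes

The synthetic-recovery study uses 160 trials, crop stride 50 (13 windows per
trial) and 15 epochs per fold — sizes chosen so the whole 4-fold protocol
completes in minutes on one CPU core while leaving a wide margin over chance
(mean accuracy 0.90 vs 0.25 in the shipped configuration). The zero-ERD control uses 5 epochs: with no
signal to fit, longer training only re-samples chance-level noise. Dense
stride-1 cropping (625 windows/trial) is the faithful full-scale setting and
is exercised by the geometry tests.

## Known limitations

* The decoder is validated on synthetic ERD only; EDF/GDF ingestion is
  provided (via mne) but no claim is made about accuracy on recorded EEG.
* The candidate-path convolution ties hidden width to the pooled feature
  width; decoupling them would require a projection the published structure
  does not contain.
* Batch-norm running statistics use momentum 0.01, so evaluation-mode
  outputs lag training statistics for the first ~100 updates; very short
  trainings are best compared in training mode or after a warm-up.
* The attention placement follows the operational equations (applied to the
  recurrent hidden sequence); prose descriptions that attach attention to
  "the input" have no corresponding formula and are not implemented
  separately.
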