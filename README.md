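# midecoder

Decoding multiclass motor imagery from EEG with an attention-based,
depthwise-separable ConvLSTM network — packaged with a synthetic ERD/ERS
signal generator so the entire pipeline is testable without any EEG download.

## Who this is for

Brain–computer-interface (BCI) researchers and students who want a compact,
fully inspectable implementation of a cropped-training EEG decoder: sliding-
window augmentation with trial-level prediction averaging, a four-block
depthwise-separable convolutional (DSC) feature extractor, a modified
bidirectional ConvLSTM with temporal attention pooling, and a 4-fold
cross-validation training protocol. Everything runs on numpy (the package
ships its own small reverse-mode autodiff engine), so there is no GPU or deep
learning framework dependency.

## The model

Imagining a movement suppresses band-limited sensorimotor rhythms (mu
8–12 Hz, beta 18–26 Hz) over the cortical patch representing the imagined
effector — event-related desynchronisation (ERD). The decoder maps a
2-second, C-channel EEG window `X ∈ ℝ^{C×T′}` to class probabilities:

1. **Sliding-window augmentation.** Each cue-locked trial (−0.5 s to 4 s) is
   sliced into windows whose starts sweep −0.5 s to 2 s; at 250 Hz with
   stride 1 that is 625 crops per trial, each trained as an independent
   example. At evaluation, per-window softmax outputs are averaged and the
   trial is predicted as `argmax(mean_w p_w)`.
2. **DSC trunk.** Block 1: a temporal convolution (F1 filters, kernel
   (1, 64)) followed by a depthwise *spatial* convolution (kernel (C, 1))
   collapsing the electrode axis — a learned filter-bank + spatial-filter
   factorisation. Blocks 2–4: separable convolutions (depthwise (1, 16) +
   pointwise (1, 1)), each ending in batch-norm, ELU, width-3 pooling
   (max-pooling, mean-pooling in the last block) and dropout. Four pools
   leave `T′ // 81` time steps.
3. **Modified ConvLSTM.** Inputs and hidden state are globally mean-pooled;
   the forget/input/output gates stay dense,
   `f_t = σ(W_xf X̃_t + W_hf H̃_{t−1} + b_f)` (likewise `i_t`, `o_t`), while
   only the candidate path is convolutional along the feature axis:
   `C̃_t = f_t · C_{t−1} + i_t · tanh(W_xc ∗ X̃_t + W_hc ∗ H̃_{t−1} + b_c)`,
   `H_t = o_t · tanh(C̃_t)`. The cell runs in both time directions and the
   two hidden streams are concatenated per step.
4. **Attention pooling.** `Z_t = tanh(W_w H_t + b_w)`,
   `a_t = softmax_t(Z_tᵀ Z_w)`, `y = Σ_t a_t H_t`, followed by a pointwise
   (1×1) convolutional classification layer and softmax.

With the calibrated defaults (F1..F4 = 8, 16, 32, 32, hidden width 32,
attention key width 26) the assembled model has **exactly 17,972 trainable
parameters**; `scripts/calibrate_params.py` reproduces that calibration.

## Worked example

```python
import midecoder as m

# 160 trials, 4 classes, 22 channels, deep (80%) ERD on lateralised channel blocks
ds = m.generate_dataset(m.SyntheticSpec(n_trials=160, erd_depth=0.8, seed=101))
crop = m.CropSpec(stride_samples=50)          # sparse crop grid: 13 windows/trial
report = m.run_experiment(ds, m.ModelConfig(seed=5), crop,
                          m.TrainConfig(max_epochs=15, early_stop_patience=15, seed=5))
print(report.per_fold_accuracy, report.mean_accuracy)
```

Output from this exact configuration (times from a single CPU core):

```
[2026-09-20 14:59:05] experiment config hash 0fd8513428f3, seed 5
[2026-09-20 15:00:52] fold 0: test accuracy 1.000 (107.1 s, 15 epochs)
[2026-09-20 15:02:44] fold 1: test accuracy 0.725 (111.2 s, 15 epochs)
[2026-09-20 15:04:37] fold 2: test accuracy 0.975 (113.0 s, 15 epochs)
[2026-09-20 15:06:30] fold 3: test accuracy 0.900 (113.2 s, 15 epochs)
[2026-09-20 15:06:30] mean accuracy over folds: 0.900
[1.0, 0.725, 0.975, 0.9] 0.9
```

Each fold trains on 80 trials, validates on 40 (early-stopping/weight
restoration on validation *trial* accuracy) and tests on 40 held-out trials;
the mean accuracy of 0.90 against a chance level of 0.25 shows the network
recovering the class-conditioned band-power suppression from raw samples.
With `erd_depth=0` (no class information) the same pipeline stays at chance
(mean accuracy 0.24 under the identical protocol).

The same flow is available from the shell:

```bash
midecoder generate --n-trials 160 --erd-depth 0.8 --seed 101 --out session.h5
midecoder crossval session.h5 --stride 50 --max-epochs 15 --report report.json
midecoder summary        # layer table + the 17,972-parameter total
```

## Documentation

`docs/methods.md` describes the generative model behind the synthetic EEG,
all numerical conventions (padding, rounding, pooling, initialisation), the
calibration of the unprinted hyperparameters, and known limitations.
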