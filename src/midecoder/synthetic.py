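"""Synthetic motor-imagery EEG with class-conditioned ERD structure.

Motor imagery suppresses band-limited sensorimotor rhythms (mu 8-12 Hz, beta
18-26 Hz) over the cortical patch representing the imagined effector
(event-related desynchronisation, ERD).  The generator emulates exactly that
physiology and nothing more: every trial carries one ongoing band-limited
oscillation per class on that class's channel subset, riding on 1/f
background noise; in a trial of class ``k`` the class-``k`` oscillation's
envelope is attenuated by ``sqrt(1 - erd_depth)`` from the cue onward, so its
*band power* drops by the factor ``(1 - erd_depth)`` relative to the pre-cue
baseline.  Which channel group desynchronises is therefore the only class
information, mirroring somatotopic lateralisation (e.g. left hand -> right
hemisphere block).

Volume conduction, montage geometry and inter-subject variability are not
modelled.  EOG/EMG-like artifact bursts can be switched on but default off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import TrialDataset
from .exceptions import ConfigurationError

__all__ = ["SyntheticSpec", "generate_dataset", "bandpower",
           "default_topographies", "default_bands", "erd_ratio_classify"]

MU_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 26.0)

# fixed rhythm strength; class structure is carried by its modulation, and the
# signal-to-noise ratio is steered through SyntheticSpec.noise_sd
RHYTHM_RMS_UV = 10.0
ERD_RAMP_S = 0.2  # raised-cosine transition at the cue, avoids a step edge


def default_topographies(n_classes: int, n_channels: int) -> list[tuple[int, ...]]:
    """Disjoint contiguous channel blocks, one per class.

    With the conventional 4-class task this mimics somatotopy: left hand ->
    right-hemisphere block, right hand -> left block, feet -> central block,
    tongue/rest -> a fourth block.
    """
    width = n_channels // n_classes
    if width < 1:
        raise ConfigurationError(
            f"n_channels={n_channels} too small for {n_classes} disjoint topographies")
    return [tuple(range(k * width, (k + 1) * width)) for k in range(n_classes)]


def default_bands(n_classes: int) -> list[tuple[float, float]]:
    """Alternate mu and beta bands across classes."""
    return [MU_BAND if k % 2 == 0 else BETA_BAND for k in range(n_classes)]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic recording session."""

    n_trials: int = 160
    n_classes: int = 4
    n_channels: int = 22
    fs: float = 250.0
    trial_duration_s: float = 4.5          # -0.5 s .. 4 s cue-relative
    t0_offset_s: float = -0.5
    class_topographies: list = field(default_factory=list)
    bands: list = field(default_factory=list)
    erd_depth: float = 0.8
    background_exponent: float = 1.0
    noise_sd: float = 5.0                  # microvolts, broadband 1/f background
    artifacts: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.class_topographies:
            self.class_topographies = default_topographies(self.n_classes, self.n_channels)
        if not self.bands:
            self.bands = default_bands(self.n_classes)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration_s))

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if abs(self.fs * self.trial_duration_s - round(self.fs * self.trial_duration_s)) > 1e-9:
            raise ConfigurationError(
                "trial_duration_s: fs * trial_duration_s must be an integer sample count")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError(f"erd_depth must lie in [0, 1], got {self.erd_depth}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if len(self.class_topographies) != self.n_classes:
            raise ConfigurationError("class_topographies: need one channel set per class")
        for k, topo in enumerate(self.class_topographies):
            if len(topo) == 0:
                raise ConfigurationError(f"class_topographies: class {k} has no channels")
            if min(topo) < 0 or max(topo) >= self.n_channels:
                raise ConfigurationError(
                    f"class_topographies: class {k} indexes outside 0..{self.n_channels - 1}")
        if len(set(map(tuple, self.class_topographies))) == 1 and self.n_classes > 1:
            raise ConfigurationError(
                "class_topographies: all classes share one topography; classes would be "
                "indistinguishable by construction")
        if len(self.bands) != self.n_classes:
            raise ConfigurationError("bands: need one (low, high) interval per class")
        for k, (lo, hi) in enumerate(self.bands):
            if not 0 < lo < hi < self.fs / 2:
                raise ConfigurationError(
                    f"bands: class {k} band ({lo}, {hi}) outside (0, Nyquist)")


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      exponent: float, sd: float, fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-sd scaled to sd."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True) + 1e-30
    return sd * x


def _band_limited_noise(rng: np.random.Generator, n: int, band: tuple, fs: float) -> np.ndarray:
    """Unit-RMS oscillation: white noise brick-wall filtered to `band`."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / (x.std() + 1e-30)


def generate_dataset(spec: SyntheticSpec) -> TrialDataset:
    """Generate a balanced, labeled ERD dataset (deterministic in spec+seed).

    Labels cycle 0..K-1 so every class appears floor/ceil(n_trials/K) times;
    when K divides n_trials the design is exactly balanced.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = spec.t0_offset_s + np.arange(n) / spec.fs

    # post-cue envelope: 1 before the cue, ramping to sqrt(1 - erd_depth) after it
    att = np.sqrt(1.0 - spec.erd_depth)
    ramp = np.clip(t / ERD_RAMP_S, 0.0, 1.0)
    envelope = 1.0 + (att - 1.0) * 0.5 * (1.0 - np.cos(np.pi * ramp))

    labels = np.arange(spec.n_trials) % spec.n_classes
    trials = np.empty((spec.n_trials, spec.n_channels, n))
    for i, y in enumerate(labels):
        x = _one_over_f_noise(rng, spec.n_channels, n, spec.background_exponent,
                              spec.noise_sd, spec.fs)
        for k in range(spec.n_classes):
            osc = RHYTHM_RMS_UV * _band_limited_noise(rng, n, spec.bands[k], spec.fs)
            if k == y:
                osc = osc * envelope
            x[list(spec.class_topographies[k])] += osc
        if spec.artifacts:
            # occasional broadband burst on a random channel (EOG/EMG-like)
            if rng.random() < 0.1:
                ch = rng.integers(spec.n_channels)
                start = rng.integers(n - int(0.2 * spec.fs))
                width = int(0.2 * spec.fs)
                x[ch, start:start + width] += 50.0 * signal.windows.hann(width)
        trials[i] = x

    return TrialDataset(trials=trials, labels=labels, fs=spec.fs,
                        t0_offset_s=spec.t0_offset_s,
                        subject_id=f"synthetic-seed{spec.seed}")


def bandpower(x: np.ndarray, fs: float, band: tuple, nperseg: int | None = None) -> float:
    """Mean spectral power of a 1-D signal inside `band`, via Welch averaging."""
    lo, hi = band
    if not 0 <= lo < hi <= fs / 2:
        raise ConfigurationError(f"band ({lo}, {hi}) outside the Nyquist range (0, {fs / 2})")
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = min(len(x), int(2 * fs))
    nperseg = min(nperseg, len(x))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(pxx[mask], freqs[mask])) if mask.sum() > 1 else float(pxx[mask].sum())


def erd_ratio_classify(ds: TrialDataset, topographies, bands,
                       baseline=(-0.5, 0.0), active=(0.5, 4.0)) -> np.ndarray:
    """Fixed (non-learned) ERD detector: for each candidate class, the ratio of
    post-cue to pre-cue band power on that class's channels; predict the class
    with the deepest suppression.  Used as a physiology-level sanity check of
    the generator, independent of the neural network."""
    fs = ds.fs
    t = ds.time_axis()
    pre = (t >= baseline[0]) & (t < baseline[1])
    post = (t >= active[0]) & (t < active[1])
    npre = int(pre.sum())
    preds = np.empty(ds.n_trials, dtype=np.int64)
    for i in range(ds.n_trials):
        ratios = []
        for topo, band in zip(topographies, bands):
            p_pre = np.mean([bandpower(ds.trials[i, c, pre], fs, band, nperseg=npre)
                             for c in topo])
            p_post = np.mean([bandpower(ds.trials[i, c, post], fs, band, nperseg=npre)
                              for c in topo])
            ratios.append(p_post / (p_pre + 1e-30))
        preds[i] = int(np.argmin(ratios))
    return preds
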