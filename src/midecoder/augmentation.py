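"""Sliding-window cropping and trial-level aggregation of window predictions.

Each cue-locked trial is sliced into many shorter overlapping windows that are
trained on as independent examples; at evaluation time the per-window class
probabilities are averaged and the trial is predicted as the argmax of that
mean.  Window starts live on the half-open cue-relative range
``[start_min_s, start_max_s)`` in steps of ``stride_samples``; with the
defaults (2 s windows starting between -0.5 s and 2 s at 250 Hz, stride one
sample) each trial yields exactly 625 crops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrialDataset
from .exceptions import AggregationError, ConfigurationError, GeometryError

__all__ = ["CropSpec", "WindowBatch", "count_windows", "crop_windows",
           "aggregate_window_predictions"]


@dataclass(frozen=True)
class CropSpec:
    """Geometry of the sliding-window augmentation (times are cue-relative)."""

    window_len_s: float = 2.0
    start_min_s: float = -0.5
    start_max_s: float = 2.0
    stride_samples: int = 1
    fs: float = 250.0

    def __post_init__(self):
        if self.window_len_s <= 0:
            raise ConfigurationError(f"window_len_s must be positive, got {self.window_len_s}")
        if self.start_min_s > self.start_max_s:
            raise ConfigurationError(
                f"start_min_s ({self.start_min_s}) exceeds start_max_s ({self.start_max_s})")
        if self.stride_samples < 1:
            raise ConfigurationError(f"stride_samples must be >= 1, got {self.stride_samples}")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")

    @property
    def window_samples(self) -> int:
        """T': window length in samples."""
        return int(round(self.window_len_s * self.fs))

    @property
    def range_samples(self) -> int:
        """Extent of the half-open start range in samples."""
        return int(round((self.start_max_s - self.start_min_s) * self.fs))


@dataclass
class WindowBatch:
    """Crops [M, C, T'] with back-pointers into the source TrialDataset."""

    windows: np.ndarray
    trial_index: np.ndarray
    labels: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def windows_per_trial(self) -> int:
        return int(np.bincount(self.trial_index).max()) if self.n_windows else 0


def count_windows(spec: CropSpec) -> int:
    """Number of crops per trial.

    Start offsets are ``0, stride, 2*stride, ...`` strictly inside the
    half-open range ``[0, range_samples)`` — i.e. ``ceil(range/stride)``, with
    the degenerate ``start_min == start_max`` case yielding a single window.
    The architecture's quoted augmentation factor (2.5 s range, 250 Hz,
    stride 1 -> 625 crops per trial) fixes this convention.
    """
    if spec.range_samples == 0:
        return 1
    return -(-spec.range_samples // spec.stride_samples)


def window_starts(spec: CropSpec, t0_offset_s: float) -> np.ndarray:
    """Start sample indices (into a trial) of every crop."""
    first = int(round((spec.start_min_s - t0_offset_s) * spec.fs))
    n = count_windows(spec)
    return first + spec.stride_samples * np.arange(n)


def crop_windows(ds: TrialDataset, spec: CropSpec) -> WindowBatch:
    """Slice every trial into its sliding windows (labels are inherited).

    Windows of one trial are contiguous in the output, ordered by start time,
    so ``windows.reshape(N, windows_per_trial, C, T')`` recovers the grouping.
    """
    starts = window_starts(spec, ds.t0_offset_s)
    t_len = spec.window_samples
    if starts[0] < 0:
        raise GeometryError(
            f"first window starts at sample {starts[0]} (t={spec.start_min_s} s), "
            "before the trial begins")
    if starts[-1] + t_len > ds.n_samples:
        bad_t = ds.t0_offset_s + starts[-1] / ds.fs
        raise GeometryError(
            f"window starting at t={bad_t:.4f} s overruns the trial "
            f"({starts[-1]} + {t_len} > {ds.n_samples} samples)")
    # one strided gather per dataset: view [N, C, n_starts_possible, T'] indexed at starts
    view = np.lib.stride_tricks.sliding_window_view(ds.trials, t_len, axis=2)
    windows = view[:, :, starts, :]                  # [N, C, W, T']
    windows = np.ascontiguousarray(windows.transpose(0, 2, 1, 3))  # [N, W, C, T']
    n_trials, w = windows.shape[0], windows.shape[1]
    return WindowBatch(
        windows=windows.reshape(n_trials * w, ds.n_channels, t_len),
        trial_index=np.repeat(np.arange(n_trials), w),
        labels=np.repeat(ds.labels, w))


def aggregate_window_predictions(window_probs: np.ndarray, reduction: str = "mean") -> np.ndarray:
    """Collapse per-window probability rows [W, K] into one trial probability.

    The trial prediction is the arithmetic mean of the window predictions,
    which is order-invariant and remains a probability vector.
    """
    window_probs = np.asarray(window_probs, dtype=float)
    if window_probs.ndim != 2 or window_probs.shape[0] == 0:
        raise AggregationError(
            f"window_probs must be a non-empty [W, K] array, got shape {window_probs.shape}")
    if (window_probs < -1e-9).any() or np.abs(window_probs.sum(axis=1) - 1.0).max() > 1e-5:
        raise AggregationError("window_probs rows must be probability vectors")
    if reduction != "mean":
        raise ConfigurationError(f"unknown reduction {reduction!r}; only 'mean' is defined")
    return window_probs.mean(axis=0)
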