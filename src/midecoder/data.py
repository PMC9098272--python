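"""Trial-level EEG data model, HDF5 persistence, and EDF/GDF epoching.

The in-memory unit is :class:`TrialDataset`: a stack of cue-locked trials
``[N, C, T_full]`` in microvolts with integer class labels and sampling
metadata.  Sample index ``s`` of a trial maps to cue-relative time
``t0_offset_s + s / fs``; all window arithmetic downstream uses this
convention with half-open intervals ``[start, start + length)``.

Persistence uses a single self-describing HDF5 file (samples + labels as
datasets, scalar metadata as attributes).  Standard EDF/GDF recordings can be
epoched into the same container through :func:`load_edf_gdf`, which requires
``mne`` (optional extra ``midecoder[edf]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .exceptions import MappingError, ValidationError

__all__ = ["TrialDataset", "save_dataset", "load_dataset", "epoch_raw", "load_edf_gdf"]


@dataclass
class TrialDataset:
    """Labeled multichannel EEG trials with sampling metadata.

    trials : float64 array [N, C, T_full], microvolts
    labels : int array [N], classes 0..K-1
    fs : sampling rate in Hz
    t0_offset_s : cue-relative time of sample 0 (default -0.5 s)
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    t0_offset_s: float = -0.5
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        self.validate()

    # -- derived geometry ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def validate(self) -> None:
        if self.trials.ndim != 3:
            raise ValidationError(f"trials must be [N, C, T], got shape {self.trials.shape}")
        if len(self.labels) != self.n_trials:
            raise ValidationError(
                f"labels length {len(self.labels)} != trial count {self.n_trials}")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative class indices")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not np.isfinite(self.trials).all():
            raise ValidationError("trials contain NaN or Inf samples")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError("channel_names length != channel count")

    def subset(self, idx) -> "TrialDataset":
        """A new dataset restricted to trial indices `idx` (copy)."""
        idx = np.asarray(idx)
        return replace(self, trials=self.trials[idx].copy(), labels=self.labels[idx].copy())

    def time_axis(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.n_samples) / self.fs

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (np.array_equal(self.trials, other.trials)
                and np.array_equal(self.labels, other.labels)
                and self.fs == other.fs
                and self.t0_offset_s == other.t0_offset_s
                and self.channel_names == other.channel_names
                and self.subject_id == other.subject_id)


def save_dataset(ds: TrialDataset, path) -> None:
    """Write a dataset to one HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ds.trials)
        f.create_dataset("labels", data=ds.labels)
        f.attrs["fs"] = float(ds.fs)
        f.attrs["t0_offset_s"] = float(ds.t0_offset_s)
        f.attrs["subject_id"] = ds.subject_id
        f.create_dataset("channel_names",
                         data=np.array(ds.channel_names, dtype=h5py.string_dtype()))


def load_dataset(path) -> TrialDataset:
    """Read a dataset written by :func:`save_dataset`, re-validating invariants."""
    try:
        with h5py.File(path, "r") as f:
            trials = f["trials"][()]
            labels = f["labels"][()]
            names = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f["channel_names"][()]]
            return TrialDataset(
                trials=trials, labels=labels, fs=float(f.attrs["fs"]),
                t0_offset_s=float(f.attrs["t0_offset_s"]),
                channel_names=names, subject_id=str(f.attrs["subject_id"]))
    except (OSError, KeyError) as exc:
        raise OSError(f"cannot read dataset container {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# EDF / GDF ingestion
# ---------------------------------------------------------------------------

def epoch_raw(raw, event_map: dict, tmin_s: float = -0.5, tmax_s: float = 4.0,
              target_fs: float = 250.0, ignore_codes=()) -> TrialDataset:
    """Cut cue-locked trials out of a continuous mne Raw recording.

    One trial per annotated cue event, spanning the half-open window
    ``[tmin_s, tmax_s)`` relative to the event (``round((tmax-tmin)*fs)``
    samples).  ``event_map`` maps annotation descriptions (or stringified GDF
    event codes) to integer class labels.  Codes present in the recording but
    absent from both ``event_map`` and ``ignore_codes`` raise
    :class:`MappingError` listing them.  Recordings at a different sampling
    rate are resampled to ``target_fs`` first.
    """
    import mne

    if abs(raw.info["sfreq"] - target_fs) > 1e-9:
        raw = raw.copy().resample(target_fs)
    fs = raw.info["sfreq"]

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    unknown = sorted(set(event_id) - set(map(str, event_map)) - set(map(str, ignore_codes)))
    if unknown:
        raise MappingError(f"event codes not in event_map: {unknown}")
    code_to_label = {event_id[str(code)]: label for code, label in event_map.items()
                     if str(code) in event_id}
    if not code_to_label:
        raise ValidationError("no mapped cue events found in the recording")

    data = raw.get_data()  # [C, T_cont]; mne returns volts for EEG channels
    if raw.info["chs"][0]["unit"] == mne.io.constants.FIFF.FIFF_UNIT_V:
        data = data * 1e6  # volts -> microvolts
    n_len = int(round((tmax_s - tmin_s) * fs))
    trials, labels = [], []
    for sample, _, code in events:
        if code not in code_to_label:
            continue
        start = sample + int(round(tmin_s * fs))
        if start < 0 or start + n_len > data.shape[1]:
            raise ValidationError(
                f"epoch window [{tmin_s}, {tmax_s}) s around sample {sample} "
                "exceeds the recording bounds")
        trials.append(data[:, start:start + n_len])
        labels.append(code_to_label[code])
    if not trials:
        raise ValidationError("no epochs produced: no mapped events present")
    return TrialDataset(
        trials=np.stack(trials), labels=np.array(labels), fs=fs, t0_offset_s=tmin_s,
        channel_names=list(raw.ch_names))


def load_edf_gdf(path, event_map: dict, tmin_s: float = -0.5, tmax_s: float = 4.0,
                 target_fs: float = 250.0, ignore_codes=()) -> TrialDataset:
    """Read an EDF or GDF recording and epoch it around its cue events."""
    import mne

    path = str(path)
    if path.lower().endswith(".gdf"):
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return epoch_raw(raw, event_map, tmin_s=tmin_s, tmax_s=tmax_s,
                     target_fs=target_fs, ignore_codes=ignore_codes)
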