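"""Training loop, 4-fold cross-validation (2 train / 1 val / 1 test), and
trial-level evaluation with window-prediction averaging.

Splitting happens at the *trial* level before any cropping, so windows from a
single trial can never straddle the train/test boundary.  Training minimises
window-level cross-entropy with Adam (the ``averaged_prob`` mode instead
averages window softmax outputs per trial before the log-loss); after each
epoch the validation *trial* accuracy is computed by averaging window
probabilities, and the best-validation weights are restored at the end.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from . import nn
from .augmentation import CropSpec, aggregate_window_predictions, crop_windows
from .autodiff import Tensor, cross_entropy, nll_of_mean_probs, softmax, tmean, reshape
from .convlstm import DSCConvLSTM, ModelConfig
from .data import TrialDataset
from .exceptions import ConfigurationError, DivergenceError, SplitError

__all__ = ["TrainConfig", "EvalReport", "kfold_split", "train", "evaluate",
           "run_experiment"]

FOLD_COUNT = 4


@dataclass
class TrainConfig:
    """Optimisation settings (values not printed by the protocol are package
    defaults, all exposed here and on the CLI)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 15
    seed: int = 0
    loss_mode: str = "per_window"   # or "averaged_prob"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            raise ConfigurationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.loss_mode not in ("per_window", "averaged_prob"):
            raise ConfigurationError(
                f"loss_mode must be 'per_window' or 'averaged_prob', got {self.loss_mode!r}")


@dataclass
class EvalReport:
    """Per-fold held-out accuracies, pooled confusion matrix, and histories."""

    per_fold_accuracy: list[float]
    confusion: np.ndarray
    training_history: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    def to_dict(self) -> dict:
        return {"per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
                "mean_accuracy": self.mean_accuracy,
                "confusion": self.confusion.tolist(),
                "training_history": self.training_history}


def kfold_split(ds: TrialDataset, seed: int = 0):
    """Partition trials into 4 class-stratified groups and yield the 4
    rotations: groups (i, i+1) train, (i+2) validation, (i+3) test (mod 4).
    Every trial takes the test role exactly once across rotations."""
    counts = np.bincount(ds.labels, minlength=ds.n_classes)
    if ds.n_trials < 2 * FOLD_COUNT or counts.min() < FOLD_COUNT:
        raise SplitError(
            f"need >= {FOLD_COUNT} trials of every class for a {FOLD_COUNT}-fold split "
            f"(class counts: {counts.tolist()})")
    skf = StratifiedKFold(n_splits=FOLD_COUNT, shuffle=True, random_state=seed)
    groups = [test for _, test in skf.split(np.zeros(ds.n_trials), ds.labels)]
    rotations = []
    for i in range(FOLD_COUNT):
        train_idx = np.concatenate([groups[i], groups[(i + 1) % FOLD_COUNT]])
        rotations.append({"train": np.sort(train_idx),
                          "val": np.sort(groups[(i + 2) % FOLD_COUNT]),
                          "test": np.sort(groups[(i + 3) % FOLD_COUNT])})
    return rotations


def _epoch_loss_per_window(model, windows, labels, order, batch_size, optimiser):
    total, seen = 0.0, 0
    for lo in range(0, len(order), batch_size):
        idx = order[lo:lo + batch_size]
        logits = model.logits(Tensor(windows[idx][:, None]))
        loss = cross_entropy(logits, labels[idx])
        optimiser.zero_grad()
        loss.backward()
        optimiser.step()
        total += loss.item() * len(idx)
        seen += len(idx)
    return total / seen


def _epoch_loss_averaged_prob(model, windows, labels, wpt, trial_order,
                              trials_per_batch, optimiser):
    """Windows of each sampled trial go through together; their softmax
    outputs are averaged per trial and the log-loss is taken on that mean."""
    total, seen = 0.0, 0
    for lo in range(0, len(trial_order), trials_per_batch):
        tidx = trial_order[lo:lo + trials_per_batch]
        widx = (tidx[:, None] * wpt + np.arange(wpt)).ravel()
        probs = softmax(model.logits(Tensor(windows[widx][:, None])), axis=1)
        k = probs.shape[1]
        trial_probs = tmean(reshape(probs, (len(tidx), wpt, k)), axis=1)
        loss = nll_of_mean_probs(trial_probs, labels[tidx * wpt])
        optimiser.zero_grad()
        loss.backward()
        optimiser.step()
        total += loss.item() * len(tidx)
        seen += len(tidx)
    return total / seen


def train(model: DSCConvLSTM, train_trials: TrialDataset, val_trials: TrialDataset,
          crop_spec: CropSpec, cfg: TrainConfig) -> tuple[DSCConvLSTM, list[dict]]:
    """Fit on cropped windows; early-stop and restore on validation trial accuracy."""
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(int(rng.integers(2 ** 31)))
    batch = crop_windows(train_trials, crop_spec)
    windows = batch.windows.astype(np.float32)
    labels = batch.labels
    wpt = batch.windows_per_trial
    val_windows = crop_windows(val_trials, crop_spec).windows.astype(np.float32)
    optimiser = nn.Adam(model.parameters(), lr=cfg.learning_rate)

    history: list[dict] = []
    best_acc, best_state, since_best = -1.0, model.state_dict(), 0
    for epoch in range(cfg.max_epochs):
        model.train()
        if cfg.loss_mode == "per_window":
            order = rng.permutation(len(windows))
            mean_loss = _epoch_loss_per_window(
                model, windows, labels, order, cfg.batch_size, optimiser)
        else:
            trials_per_batch = max(1, cfg.batch_size // wpt)
            trial_order = rng.permutation(train_trials.n_trials)
            mean_loss = _epoch_loss_averaged_prob(
                model, windows, labels, wpt, trial_order, trials_per_batch, optimiser)
        if not np.isfinite(mean_loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        val_acc, _ = _trial_accuracy(model, val_trials, crop_spec,
                                     cached_windows=val_windows)
        history.append({"epoch": epoch, "train_loss": float(mean_loss),
                        "val_trial_accuracy": float(val_acc)})
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def _trial_accuracy(model: DSCConvLSTM, trials: TrialDataset, crop_spec: CropSpec,
                    cached_windows: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    model.eval()
    if cached_windows is None:
        cached_windows = crop_windows(trials, crop_spec).windows.astype(np.float32)
    probs = model.predict_proba(cached_windows)
    wpt = len(cached_windows) // trials.n_trials
    trial_probs = np.stack([
        aggregate_window_predictions(probs[i * wpt:(i + 1) * wpt])
        for i in range(trials.n_trials)])
    preds = trial_probs.argmax(axis=1)
    return float((preds == trials.labels).mean()), preds


def evaluate(model: DSCConvLSTM, test_trials: TrialDataset,
             crop_spec: CropSpec) -> dict:
    """Trial-level accuracy and confusion matrix via mean-probability voting."""
    n_model_classes = model.cfg.n_classes
    if test_trials.n_classes > n_model_classes:
        raise ConfigurationError(
            f"test labels reach class {test_trials.n_classes - 1} but the model "
            f"outputs only {n_model_classes} classes")
    acc, preds = _trial_accuracy(model, test_trials, crop_spec)
    conf = confusion_matrix(test_trials.labels, preds, labels=range(n_model_classes))
    return {"accuracy": acc, "confusion": conf, "predictions": preds}


def run_experiment(ds: TrialDataset, model_cfg: ModelConfig, crop_spec: CropSpec,
                   train_cfg: TrainConfig, out_path=None, log=print) -> EvalReport:
    """The full 4-fold protocol: split, train one model per rotation, pool."""
    rotations = kfold_split(ds, seed=train_cfg.seed)
    cfg_hash = hashlib.sha256(json.dumps(
        {"model": model_cfg.to_dict(), "crop": vars(crop_spec),
         "train": vars(train_cfg)}, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def stamp(msg):
        log(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    stamp(f"experiment config hash {cfg_hash}, seed {train_cfg.seed}")

    accs, histories = [], []
    confusion = np.zeros((model_cfg.n_classes, model_cfg.n_classes), dtype=int)
    for i, rot in enumerate(rotations):
        t0 = time.time()
        fold_cfg = ModelConfig.from_dict(model_cfg.to_dict())
        fold_cfg.seed = model_cfg.seed + i
        model = DSCConvLSTM(fold_cfg)
        fold_train = TrainConfig(**{**vars(train_cfg), "seed": train_cfg.seed + i})
        model, history = train(model, ds.subset(rot["train"]), ds.subset(rot["val"]),
                               crop_spec, fold_train)
        result = evaluate(model, ds.subset(rot["test"]), crop_spec)
        accs.append(result["accuracy"])
        confusion += result["confusion"]
        histories.append(history)
        stamp(f"fold {i}: test accuracy {result['accuracy']:.3f} "
              f"({time.time() - t0:.1f} s, {len(history)} epochs)")

    report = EvalReport(per_fold_accuracy=accs, confusion=confusion,
                        training_history=histories)
    stamp(f"mean accuracy over folds: {report.mean_accuracy:.3f}")
    if out_path is not None:
        with open(out_path, "w") as f:
            json.dump({"config_hash": cfg_hash, **report.to_dict()}, f, indent=2)
        with open(str(out_path) + ".txt", "w") as f:
            f.write(f"config hash: {cfg_hash}\n")
            for i, a in enumerate(accs):
                f.write(f"fold {i}: test trial accuracy {a:.4f}\n")
            f.write(f"mean accuracy: {report.mean_accuracy:.4f}\n")
            f.write("confusion (rows = true class):\n")
            for row in confusion:
                f.write("  " + " ".join(f"{int(v):5d}" for v in row) + "\n")
    return report
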