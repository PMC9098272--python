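"""Modified ConvLSTM cell, temporal attention pooling, and the full decoder.

The recurrent cell departs from a standard LSTM in three ways:

* inputs and the previous hidden state are **globally mean-pooled** over their
  spatial extent before entering the cell, so gates operate on per-map scalars;
* the three gates (forget, input, output) stay **dense**, while only the
  candidate path is **convolutional**: a short 1-D kernel slides along the
  feature axis of the pooled input and hidden vectors (this requires the
  hidden width to equal the pooled feature width);
* the candidate already blends the previous memory, ``C~_t = f_t * C_{t-1} +
  i_t * tanh(W_xc * x~_t + W_hc * h~_{t-1} + b_c)``, and is carried forward
  directly as the next cell memory, with ``H_t = o_t * tanh(C~_t)``.

The cell is run forward and backward over the backbone's time axis, the two
hidden streams are concatenated per step, a learned softmax attention over
time collapses the sequence to one vector, and a pointwise (1x1) convolutional
classification layer maps it to class logits (softmax on top).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .backbone import BackboneConfig, DSCBackbone, output_time_length
from .exceptions import AssemblyError, ConfigurationError

__all__ = ["RecurrentSpec", "AttentionSpec", "ModelConfig", "ConvLSTMParams",
           "AttentionParams", "ConvLSTMCell", "AttentionPool", "DSCConvLSTM",
           "convlstm_step", "run_convlstm", "bidirectional_fuse", "attention_pool",
           "build_model"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrentSpec:
    """Hidden width, candidate-path kernel, and direction switches."""

    hidden_size: int = 32
    candidate_kernel: int = 3
    bidirectional: bool = True

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ConfigurationError(f"hidden_size must be >= 1, got {self.hidden_size}")
        if self.candidate_kernel < 1 or self.candidate_kernel % 2 == 0:
            raise ConfigurationError(
                f"candidate_kernel must be odd and >= 1, got {self.candidate_kernel}")


@dataclass(frozen=True)
class AttentionSpec:
    """Width of the attention key space."""

    key_dim: int = 26

    def __post_init__(self):
        if self.key_dim < 1:
            raise ConfigurationError(f"key_dim must be >= 1, got {self.key_dim}")


@dataclass
class ModelConfig:
    """Everything needed to assemble (and re-assemble) the full classifier."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    recurrent: RecurrentSpec = field(default_factory=RecurrentSpec)
    attention: AttentionSpec = field(default_factory=AttentionSpec)
    n_classes: int = 4
    use_recurrent_head: bool = True   # ablation: backbone + classifier only
    use_attention: bool = True        # ablation: mean over time instead
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "backbone": vars(self.backbone).copy(),
            "recurrent": vars(self.recurrent).copy(),
            "attention": vars(self.attention).copy(),
            "n_classes": self.n_classes,
            "use_recurrent_head": self.use_recurrent_head,
            "use_attention": self.use_attention,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(backbone=BackboneConfig(**d["backbone"]),
                   recurrent=RecurrentSpec(**d["recurrent"]),
                   attention=AttentionSpec(**d["attention"]),
                   n_classes=int(d["n_classes"]),
                   use_recurrent_head=bool(d["use_recurrent_head"]),
                   use_attention=bool(d["use_attention"]),
                   seed=int(d["seed"]))


# ---------------------------------------------------------------------------
# plain-array parameter views (functional API)
# ---------------------------------------------------------------------------

@dataclass
class ConvLSTMParams:
    """All weights of one direction's cell, as plain arrays.

    Gate weights map the pooled input (w_x*: [n_x, n_h]) and pooled hidden
    state (w_h*: [n_h, n_h]) densely to the hidden units; the candidate path
    holds two short 1-D kernels applied along the feature axis.
    """

    w_xf: np.ndarray
    w_hf: np.ndarray
    b_f: np.ndarray
    w_xi: np.ndarray
    w_hi: np.ndarray
    b_i: np.ndarray
    w_xo: np.ndarray
    w_ho: np.ndarray
    b_o: np.ndarray
    w_xc: np.ndarray
    w_hc: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.w_hf.shape[0]


@dataclass
class AttentionParams:
    """Attention weights: key map w_w [width, d_k], bias b_w [d_k], context z_w [d_k]."""

    w_w: np.ndarray
    b_w: np.ndarray
    z_w: np.ndarray


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ConvLSTMCell(nn.Module):
    """One direction of the modified cell (dense gates, convolutional candidate)."""

    def __init__(self, input_size: int, spec: RecurrentSpec,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if spec.hidden_size != input_size:
            raise AssemblyError(
                f"hidden_size ({spec.hidden_size}) must equal the pooled feature width "
                f"({input_size}): the candidate-path convolution is length-preserving "
                "along the feature axis")
        rng = rng or np.random.default_rng(0)
        n = spec.hidden_size
        self.spec = spec
        self.input_size = input_size

        def dense_x():
            return nn.Parameter(nn.uniform_fan_in(rng, (input_size, n), input_size))

        self.w_xf, self.w_xi, self.w_xo = dense_x(), dense_x(), dense_x()
        # recurrent (state-to-state) maps start orthogonal
        self.w_hf = nn.Parameter(nn.orthogonal(rng, n))
        self.w_hi = nn.Parameter(nn.orthogonal(rng, n))
        self.w_ho = nn.Parameter(nn.orthogonal(rng, n))
        self.b_f = nn.Parameter(np.zeros(n))
        self.b_i = nn.Parameter(np.zeros(n))
        self.b_o = nn.Parameter(np.zeros(n))
        k = spec.candidate_kernel
        self.w_xc = nn.Parameter(nn.uniform_fan_in(rng, (k,), k))
        self.w_hc = nn.Parameter(nn.uniform_fan_in(rng, (k,), k))
        self.b_c = nn.Parameter(np.zeros(n))

    def initial_state(self, batch: int) -> tuple[Tensor, Tensor]:
        n = self.spec.hidden_size
        zero = np.zeros((batch, n), dtype=ad.DTYPE)
        return Tensor(zero), Tensor(zero)

    @staticmethod
    def _pool(x: Tensor) -> Tensor:
        """Global mean pooling over any spatial extent beyond [B, maps]."""
        if x.ndim == 2:
            return x
        return ad.tmean(x, axis=tuple(range(2, x.ndim)))

    def step(self, x_t: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, Tensor]:
        """One recurrence step; returns (H_t, C_t) with C_t = C~_t."""
        h_prev, c_prev = state
        xt = self._pool(x_t)
        ht = self._pool(h_prev)
        f = ad.sigmoid(xt @ self.w_xf + ht @ self.w_hf + self.b_f)
        i = ad.sigmoid(xt @ self.w_xi + ht @ self.w_hi + self.b_i)
        cand = ad.tanh(ad.conv1d_feature(xt, self.w_xc)
                       + ad.conv1d_feature(ht, self.w_hc) + self.b_c)
        c = f * c_prev + i * cand
        o = ad.sigmoid(xt @ self.w_xo + ht @ self.w_ho + self.b_o)
        h = o * ad.tanh(c)
        return h, c

    forward = step

    # -- plain-array views ---------------------------------------------------
    def export_params(self) -> ConvLSTMParams:
        return ConvLSTMParams(
            w_xf=self.w_xf.data.copy(), w_hf=self.w_hf.data.copy(), b_f=self.b_f.data.copy(),
            w_xi=self.w_xi.data.copy(), w_hi=self.w_hi.data.copy(), b_i=self.b_i.data.copy(),
            w_xo=self.w_xo.data.copy(), w_ho=self.w_ho.data.copy(), b_o=self.b_o.data.copy(),
            w_xc=self.w_xc.data.copy(), w_hc=self.w_hc.data.copy(), b_c=self.b_c.data.copy())

    @classmethod
    def from_params(cls, params: ConvLSTMParams) -> "ConvLSTMCell":
        n = params.hidden_size
        spec = RecurrentSpec(hidden_size=n, candidate_kernel=len(params.w_xc))
        cell = cls(params.w_xf.shape[0], spec)
        for name in ("w_xf", "w_hf", "b_f", "w_xi", "w_hi", "b_i",
                     "w_xo", "w_ho", "b_o", "w_xc", "w_hc", "b_c"):
            arr = np.asarray(getattr(params, name), dtype=ad.DTYPE)
            want = getattr(cell, name).data.shape
            if arr.shape != want:
                raise AssemblyError(f"parameter {name}: shape {arr.shape} != expected {want}")
            getattr(cell, name).data = arr.copy()
        return cell


class AttentionPool(nn.Module):
    """Softmax attention over time: keys Z_t = tanh(W_w H_t + b_w), scores
    Z_t . Z_w, weights a_t = softmax_t(scores), output y = sum_t a_t H_t."""

    def __init__(self, width: int, spec: AttentionSpec,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w_w = nn.Parameter(nn.uniform_fan_in(rng, (width, spec.key_dim), width))
        self.b_w = nn.Parameter(np.zeros(spec.key_dim))
        self.z_w = nn.Parameter(nn.uniform_fan_in(rng, (spec.key_dim,), spec.key_dim))

    def forward(self, h_seq: Tensor) -> tuple[Tensor, Tensor]:
        """h_seq: [B, T, width] -> (pooled [B, width], weights [B, T])."""
        keys = ad.tanh(h_seq @ self.w_w + self.b_w)          # [B, T, d_k]
        scores = keys @ ad.reshape(self.z_w, (-1, 1))        # [B, T, 1]
        b, t = scores.shape[0], scores.shape[1]
        a = ad.softmax(ad.reshape(scores, (b, t)), axis=1)   # [B, T]
        weighted = ad.reshape(a, (b, t, 1)) * h_seq
        return ad.tsum(weighted, axis=1), a

    def export_params(self) -> AttentionParams:
        return AttentionParams(w_w=self.w_w.data.copy(), b_w=self.b_w.data.copy(),
                               z_w=self.z_w.data.copy())

    @classmethod
    def from_params(cls, params: AttentionParams) -> "AttentionPool":
        width, d_k = params.w_w.shape
        pool = cls(width, AttentionSpec(key_dim=d_k))
        pool.w_w.data = np.asarray(params.w_w, dtype=ad.DTYPE).copy()
        pool.b_w.data = np.asarray(params.b_w, dtype=ad.DTYPE).copy()
        pool.z_w.data = np.asarray(params.z_w, dtype=ad.DTYPE).copy()
        return pool


# ---------------------------------------------------------------------------
# functional operations (plain-array in, plain-array out)
# ---------------------------------------------------------------------------

def convlstm_step(x_t: np.ndarray, state: tuple, params: ConvLSTMParams) -> tuple:
    """Evaluate one cell step on arrays; returns (H_t, C_t) as arrays.

    ``x_t`` may be [B, maps] or [B, maps, H, W] (pooled internally); ``state``
    is an (H_{t-1}, C_{t-1}) pair of [B, hidden] arrays.
    """
    cell = ConvLSTMCell.from_params(params)
    h, c = cell.step(Tensor(np.asarray(x_t)),
                     (Tensor(np.asarray(state[0])), Tensor(np.asarray(state[1]))))
    return h.data.copy(), c.data.copy()


def run_convlstm(sequence, params: ConvLSTMParams, direction: str = "forward") -> np.ndarray:
    """Run the cell from a zero state over a [T, B, maps] (or [T, maps]) sequence.

    The backward direction consumes the reversed sequence and the returned
    hidden states are re-aligned to the original time order; both directions
    therefore return ``[T, B, hidden]`` indexed by original time.
    """
    seq = [np.atleast_2d(np.asarray(x)) for x in sequence]
    if len(seq) == 0:
        raise ConfigurationError("run_convlstm needs a non-empty sequence")
    if direction not in ("forward", "backward"):
        raise ConfigurationError(f"direction must be 'forward' or 'backward', got {direction!r}")
    if direction == "backward":
        seq = seq[::-1]
    cell = ConvLSTMCell.from_params(params)
    state = cell.initial_state(seq[0].shape[0])
    out = []
    for x_t in seq:
        state = cell.step(Tensor(x_t), state)
        out.append(state[0].data.copy())
    if direction == "backward":
        out = out[::-1]
    return np.stack(out)


def bidirectional_fuse(h_fwd: np.ndarray, h_bwd: np.ndarray) -> np.ndarray:
    """Per-time-step concatenation of the two hidden streams along features."""
    h_fwd, h_bwd = np.asarray(h_fwd), np.asarray(h_bwd)
    if h_fwd.shape != h_bwd.shape:
        raise AssemblyError(
            f"cannot fuse hidden sequences of shapes {h_fwd.shape} and {h_bwd.shape}")
    return np.concatenate([h_fwd, h_bwd], axis=-1)


def attention_pool(h_seq: np.ndarray, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Functional attention pooling of a [T, width] (or [B, T, width]) sequence.

    Returns ``(y, a)``: the pooled vector(s) and the attention weights.
    """
    h = np.asarray(h_seq, dtype=float)
    squeeze = h.ndim == 2
    if squeeze:
        h = h[None]
    pool = AttentionPool.from_params(params)
    y, a = pool(Tensor(h))
    y, a = y.data.copy(), a.data.copy()
    return (y[0], a[0]) if squeeze else (y, a)


# ---------------------------------------------------------------------------
# full classifier
# ---------------------------------------------------------------------------

class DSCConvLSTM(nn.Module):
    """Backbone -> bidirectional ConvLSTM over the pooled time axis ->
    attention pooling -> 1x1 convolutional classification layer -> softmax."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.backbone = DSCBackbone(cfg.backbone, rng=rng)
        feat = cfg.backbone.out_maps
        if cfg.use_recurrent_head:
            self.fwd_cell = ConvLSTMCell(feat, cfg.recurrent, rng=rng)
            self.bwd_cell = (ConvLSTMCell(feat, cfg.recurrent, rng=rng)
                             if cfg.recurrent.bidirectional else None)
            width = cfg.recurrent.hidden_size * (2 if cfg.recurrent.bidirectional else 1)
            self.attention = (AttentionPool(width, cfg.attention, rng=rng)
                              if cfg.use_attention else None)
        else:
            self.fwd_cell = self.bwd_cell = self.attention = None
            width = feat
        # the pointwise classification layer: a (1,1) convolution on a 1x1 map,
        # i.e. a dense map with bias
        self.classifier = nn.Linear(width, cfg.n_classes, bias=True, rng=rng)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = self._dropout_rng

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = self._dropout_rng

    # -- forward -------------------------------------------------------------
    def _run_direction(self, steps: list[Tensor], cell: ConvLSTMCell,
                       reverse: bool) -> list[Tensor]:
        order = range(len(steps) - 1, -1, -1) if reverse else range(len(steps))
        state = cell.initial_state(steps[0].shape[0])
        hs: list[Tensor] = []
        for t in order:
            state = cell.step(steps[t], state)
            hs.append(state[0])
        return hs[::-1] if reverse else hs

    def logits(self, x: Tensor) -> Tensor:
        fm = self.backbone(x)                        # [B, maps, 1, T_out]
        if self.fwd_cell is None:
            pooled = ad.tmean(fm, axis=(2, 3))
            return self.classifier(pooled)
        b, maps, _, t_out = fm.shape
        steps = [fm[:, :, :, t:t + 1] for t in range(t_out)]
        h_fwd = self._run_direction(steps, self.fwd_cell, reverse=False)
        if self.bwd_cell is not None:
            h_bwd = self._run_direction(steps, self.bwd_cell, reverse=True)
            fused = [ad.concat([hf, hb], axis=1) for hf, hb in zip(h_fwd, h_bwd)]
        else:
            fused = h_fwd
        width = fused[0].shape[1]
        h_seq = ad.concat([ad.reshape(h, (b, 1, width)) for h in fused], axis=1)
        if self.attention is not None:
            pooled, _ = self.attention(h_seq)
        else:
            pooled = ad.tmean(h_seq, axis=1)
        return self.classifier(pooled)

    def forward(self, x: Tensor) -> Tensor:
        """Class probabilities per window: softmax over the classifier logits."""
        return ad.softmax(self.logits(x), axis=1)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Numpy convenience wrapper used at evaluation time (no grad tape).

        The batch size bounds the temporal convolution's unfolded workspace;
        64 keeps it below ~200 MB for 22-channel 2 s windows."""
        windows = np.asarray(windows)
        if windows.ndim == 3:
            windows = windows[:, None]
        out = []
        with ad.no_grad():
            for lo in range(0, len(windows), batch_size):
                probs = self.forward(Tensor(windows[lo:lo + batch_size]))
                out.append(probs.data.copy())
        return np.concatenate(out, axis=0)

    def output_time_length(self, t_in: int) -> int:
        return output_time_length(self.cfg.backbone, t_in)


def build_model(backbone_cfg: BackboneConfig | None = None,
                recurrent_spec: RecurrentSpec | None = None,
                attention_spec: AttentionSpec | None = None,
                n_classes: int = 4, **flags) -> DSCConvLSTM:
    """Assemble the full classifier from component specs (defaults are the
    calibrated configuration)."""
    cfg = ModelConfig(backbone=backbone_cfg or BackboneConfig(),
                      recurrent=recurrent_spec or RecurrentSpec(),
                      attention=attention_spec or AttentionSpec(),
                      n_classes=n_classes, **flags)
    return DSCConvLSTM(cfg)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DSCConvLSTM, path) -> None:
    """Serialise weights + the full config into one .npz archive."""
    import json

    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DSCConvLSTM:
    import json

    with np.load(path) as archive:
        cfg = ModelConfig.from_dict(json.loads(bytes(archive["__config__"].tobytes()).decode()))
        model = DSCConvLSTM(cfg)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model
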