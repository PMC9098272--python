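"""Four-block depthwise-separable convolutional feature extractor.

Block 1 factorises the first stage into a temporal convolution (F1 bandpass-
like filters of width 64 samples, length-preserving) followed by a depthwise
*spatial* convolution spanning the full electrode axis (kernel (C, 1)), which
collapses the electrode dimension to 1 — the FBCSP-inspired split of
time-domain filtering and spatial filtering.  Blocks 2-4 are separable
convolutions: a grouped depthwise temporal convolution of width 16 followed
by a pointwise (1, 1) map, then batch-norm, ELU, width-3 pooling and dropout.
Blocks 1-3 max-pool; block 4 mean-pools.  Each pooling stage floor-divides
the time axis by 3, so a T'-sample window leaves T' // 81 time steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor
from .exceptions import ConfigurationError, GeometryError

__all__ = ["BackboneConfig", "DSCBackbone", "build_backbone", "count_parameters",
           "output_time_length"]


@dataclass(frozen=True)
class BackboneConfig:
    """Hyperparameters of the convolutional trunk.

    The filter counts F1..F4 and the depth multiplier D fix the trunk's
    capacity; the defaults are the repository's calibrated configuration
    (see :mod:`midecoder.calibration`).
    """

    n_channels: int = 22
    f1: int = 8
    f2: int = 16
    f3: int = 32
    f4: int = 32
    depth_multiplier: int = 1
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool: int = 3
    dropout_p: float = 0.25
    bn_eps: float = 1e-3
    bn_momentum: float = 0.01

    def __post_init__(self):
        for name in ("f1", "f2", "f3", "f4"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.depth_multiplier < 1:
            raise ConfigurationError(f"depth_multiplier must be >= 1, got {self.depth_multiplier}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError(f"dropout_p must lie in [0, 1), got {self.dropout_p}")
        if self.temporal_kernel < 1 or self.separable_kernel < 1:
            raise ConfigurationError("kernel widths must be >= 1")
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")

    @property
    def out_maps(self) -> int:
        """Feature maps leaving block 4 (= D * F4)."""
        return self.depth_multiplier * self.f4


def output_time_length(cfg: BackboneConfig, t_in: int) -> int:
    """Time steps surviving the four pool-by-3 stages; raises GeometryError
    (naming the failing stage) if any stage would pool an empty axis."""
    t = t_in
    for block in range(1, 5):
        if t < cfg.pool:
            raise GeometryError(
                f"block {block} pooling needs >= {cfg.pool} time samples, has {t} "
                f"(input window of {t_in} samples is too short)")
        t //= cfg.pool
    return t


class DSCBackbone(nn.Module):
    """[B, 1, C, T'] -> [B, D*F4, 1, T' // 81] feature maps."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        d = cfg.depth_multiplier
        pad_t = ((0, 0), nn.same_padding(cfg.temporal_kernel))
        pad_s = ((0, 0), nn.same_padding(cfg.separable_kernel))

        # Block 1: temporal filters, then a full-height depthwise spatial filter
        self.conv_time = nn.Conv2d(1, cfg.f1, (1, cfg.temporal_kernel), padding=pad_t, rng=rng)
        self.bn_time = nn.BatchNorm2d(cfg.f1, eps=cfg.bn_eps, momentum=cfg.bn_momentum)
        self.conv_spat = nn.Conv2d(cfg.f1, d * cfg.f1, (cfg.n_channels, 1),
                                   groups=cfg.f1, rng=rng)
        self.bn_spat = nn.BatchNorm2d(d * cfg.f1, eps=cfg.bn_eps, momentum=cfg.bn_momentum)

        # Blocks 2-4: depthwise temporal + pointwise, i.e. separable convolutions
        widths = [d * cfg.f1, d * cfg.f2, d * cfg.f3, d * cfg.f4]
        self.depthwise = [
            nn.Conv2d(widths[i], widths[i], (1, cfg.separable_kernel),
                      padding=pad_s, groups=widths[i], rng=rng)
            for i in range(3)]
        self.pointwise = [
            nn.Conv2d(widths[i], widths[i + 1], (1, 1), rng=rng) for i in range(3)]
        self.bns = [nn.BatchNorm2d(widths[i + 1], eps=cfg.bn_eps, momentum=cfg.bn_momentum)
                    for i in range(3)]

        self.elu = nn.ELU()
        self.maxpool = nn.MaxPoolW(cfg.pool)
        self.avgpool = nn.AvgPoolW(cfg.pool)
        self.dropouts = [nn.Dropout(cfg.dropout_p) for _ in range(4)]

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != cfg.n_channels:
            raise GeometryError(
                f"backbone expects input [B, 1, {cfg.n_channels}, T'], got {x.shape}")
        output_time_length(cfg, x.shape[3])  # fail early with the stage name

        h = self.conv_time(x)
        h = self.bn_time(h)
        h = self.conv_spat(h)          # electrode axis -> extent 1
        h = self.bn_spat(h)
        h = self.elu(h)
        h = self.maxpool(h)
        h = self.dropouts[0](h)
        for i in range(3):
            h = self.depthwise[i](h)
            h = self.pointwise[i](h)
            h = self.bns[i](h)
            h = self.elu(h)
            h = self.avgpool(h) if i == 2 else self.maxpool(h)
            h = self.dropouts[i + 1](h)
        return h


def build_backbone(cfg: BackboneConfig, rng: np.random.Generator | None = None) -> DSCBackbone:
    """Construct the trunk (validated by the config's own invariants)."""
    return DSCBackbone(cfg, rng=rng)


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalars (conv kernels, affine batch-norm pairs,
    recurrent/attention weights, classifier weights and biases)."""
    return model.count_parameters()
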