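"""Network architectures mapping an N-length expression profile to an
N-length PE-probability vector.

Three interchangeable builders share one configuration surface so that the
model comparison is a pure architecture swap:

``pspnet``
    Batch norm -> strided convolution feature extractor -> pyramid pooling
    (multi-bin max-pooled context branches, upsampled and concatenated) ->
    convolutional fusion with dropout -> transposed convolution restoring
    the indicator axis -> per-position dense head -> squashed output.
``cnn``
    The same backbone without the pyramid branches.
``mlp``
    Two 128-unit fully connected hidden layers with dropout.

The convolutional kernels are one-dimensional (length ``kernel``) because
inputs are 1 x N profile vectors, not images. Outputs are squashed to
[0, 1] by a logistic layer by default (hard clamping is available), since
the targets are probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ..io import ValidationError
from .layers import (
    Crop1d,
    AdaptiveMaxPool1d,
    AddChannel,
    BatchNorm,
    Clamp,
    Conv1d,
    ConvTranspose1d,
    Dense,
    Dropout,
    Flatten,
    Module,
    Parameter,
    PyramidPooling,
    ReLU,
    Sequential,
    Sigmoid,
    SqueezeChannel,
)

logger = logging.getLogger(__name__)

ARCHS = ("pspnet", "cnn", "mlp")


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    Defaults follow the reference design: length-3 kernels, 128 channels,
    stride 5, pyramid bins [1, 2, 3, 6], dropout 0.25, batch norm before
    each convolution. Bins larger than the post-stride feature length are
    pruned with a warning.
    """

    kernel: int = 3
    channels: int = 128
    stride: int = 5
    pyramid_bins: list[int] = field(default_factory=lambda: [1, 2, 3, 6])
    dropout: float = 0.25
    batch_norm: bool = True
    output_activation: str = "logistic_squash"
    arch: str = "pspnet"

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValidationError("kernel must be odd")
        if self.channels < 1 or self.stride < 1:
            raise ValidationError("channels and stride must be >= 1")
        if list(self.pyramid_bins) != sorted(set(self.pyramid_bins)):
            raise ValidationError("pyramid_bins must be strictly increasing")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.output_activation not in ("logistic_squash", "clamp"):
            raise ValidationError(
                f"unknown output_activation {self.output_activation!r}"
            )
        if self.arch not in ARCHS:
            raise ValidationError(f"arch must be one of {ARCHS}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(**d)


class Network(Module):
    """A built architecture with a fixed input length N.

    Accepts ``(batch, N)`` or ``(batch, 1, N)`` input and emits
    ``(batch, N)`` probabilities in [0, 1].
    """

    def __init__(self, net: Sequential, config: NetConfig, N: int, conv_input: bool) -> None:
        self.net = net
        self.config = config
        self.N = N
        self.conv_input = conv_input

    def modules(self) -> list[Module]:
        return [self] + self.net.modules()

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def _shape_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != self.N:
                raise ValidationError(
                    f"input has {x.shape[1]} indicators, model expects {self.N}"
                )
            return x[:, None, :] if self.conv_input else x
        if x.ndim == 3 and x.shape[1] == 1 and x.shape[2] == self.N:
            return x if self.conv_input else x[:, 0, :]
        raise ValidationError(f"cannot interpret input of shape {x.shape}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(self._shape_input(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def reseed_dropout(self, seed_sequence: np.random.SeedSequence) -> None:
        drops = [m for m in self.net.modules() if isinstance(m, Dropout)]
        for m, child in zip(drops, seed_sequence.spawn(max(1, len(drops)))):
            m.rng = np.random.default_rng(child)


def _output_layer(cfg: NetConfig) -> Module:
    return Sigmoid() if cfg.output_activation == "logistic_squash" else Clamp()


def _pruned_bins(cfg: NetConfig, feature_length: int) -> list[int]:
    bins = [b for b in cfg.pyramid_bins if b <= feature_length]
    if not bins:
        raise ValidationError(
            f"all pyramid bins {cfg.pyramid_bins} exceed feature length "
            f"{feature_length}"
        )
    if len(bins) < len(cfg.pyramid_bins):
        logger.warning(
            "pyramid bins %s pruned to %s for feature length %d",
            cfg.pyramid_bins, bins, feature_length,
        )
    return bins


def build_model(cfg: NetConfig, N: int, seed: int = 0) -> Network:
    """Construct an untrained network for N indicators, seeded weights."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ch, k, s = cfg.channels, cfg.kernel, cfg.stride

    if cfg.arch == "mlp":
        layers = [
            Flatten(),
            Dense(N, ch, rng=rng),
            ReLU(),
            Dropout(cfg.dropout),
            Dense(ch, ch, rng=rng),
            ReLU(),
            Dense(ch, N, rng=rng),
            _output_layer(cfg),
        ]
        return Network(Sequential(*layers), cfg, N, conv_input=False)

    # the downsampling convolution needs a kernel at least as wide as its
    # stride, else 1 - kernel/stride of the input positions are skipped
    # outright and their targets become unpredictable
    k_down = max(k, s)
    pad = (k_down - 1) // 2
    feature_len = (N + 2 * pad - k_down) // s + 1
    if feature_len < 1:
        raise ValidationError(f"stride {s} collapses an input of length {N}")
    # restoring transposed convolution: the kernel must be at least one
    # stride wide so every output position receives input (kernel < stride
    # leaves gaps fed only by the bias); the extra stride of output is
    # centre-cropped back to N
    k_up = N - (feature_len - 1) * s + s
    crop_total = (feature_len - 1) * s + k_up - N
    layers: list[Module] = []
    if cfg.batch_norm:
        # normalise each indicator position separately: abundances span
        # several decades across indicators, so a joint (single-channel)
        # normalisation would leave the per-position scales wildly mixed
        layers.append(BatchNorm(N))
    layers += [
        AddChannel(),
        Conv1d(1, ch, kernel=k_down, stride=s, padding=pad, rng=rng),
        ReLU(),
    ]

    fused_channels = ch
    if cfg.arch == "pspnet":
        bins = _pruned_bins(cfg, feature_len)
        branch_channels = max(1, ch // len(bins))
        pyramid = PyramidPooling(ch, feature_len, bins, branch_channels, rng=rng)
        layers.append(pyramid)
        fused_channels = pyramid.out_channels

    if cfg.batch_norm:
        layers.append(BatchNorm(fused_channels))
    layers += [
        Conv1d(fused_channels, ch, kernel=k, stride=1, padding=pad, rng=rng),
        ReLU(),
        Dropout(cfg.dropout),
        ConvTranspose1d(ch, ch, kernel=k_up, stride=s, rng=rng),
        Crop1d(crop_total // 2, N),
        # per-position dense head: 1x1 convolution, 128 channels
        Conv1d(ch, ch, kernel=1, rng=rng),
        ReLU(),
        Conv1d(ch, 1, kernel=1, rng=rng),
        _output_layer(cfg),
        SqueezeChannel(),
    ]
    return Network(Sequential(*layers), cfg, N, conv_input=False)
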