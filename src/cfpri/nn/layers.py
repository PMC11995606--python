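"""Minimal NumPy neural-network layers with explicit backpropagation.

Everything operates on small 1-D profiles, so the implementation favours
clarity over micro-optimisation: convolutions are computed as a short loop
over kernel taps with an einsum per tap, which is fast for kernels of
length <= 5 and feature maps of length <= a few hundred.

Array conventions: convolutional layers take ``(batch, channels, length)``;
dense layers take ``(batch, features)``. Each layer caches what its
``backward`` needs during ``forward``; gradients accumulate into
``Parameter.grad`` and are consumed by an optimiser.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    """Base layer: forward caches, backward returns grad w.r.t. input."""

    training: bool = False

    def parameters(self) -> list[Parameter]:
        return []

    def modules(self) -> list["Module"]:
        return [self]

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def modules(self) -> list[Module]:
        out: list[Module] = [self]
        for layer in self.layers:
            out.extend(layer.modules())
        return out

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """1-D cross-correlation with zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel
        self.W = Parameter(_he_init(rng, (out_channels, in_channels, kernel), fan_in), "conv.W")
        self.b = Parameter(np.zeros(out_channels), "conv.b")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def out_length(self, length: int) -> int:
        return (length + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        p, s, k = self.padding, self.stride, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        Lout = self.out_length(L)
        y = np.broadcast_to(
            self.b.value[None, :, None], (B, self.out_channels, Lout)
        ).copy()
        end = s * (Lout - 1) + 1
        for t in range(k):
            xs = xp[:, :, t : t + end : s]
            # y[b,o,l] += sum_c W[o,c,t] x[b,c,l]: batched matmul hits BLAS
            y += np.matmul(self.W.value[:, :, t], xs)
        self._cache = (xp, L, Lout)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, L, Lout = self._cache
        p, s, k = self.padding, self.stride, self.kernel
        self.b.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        end = s * (Lout - 1) + 1
        for t in range(k):
            xs = xp[:, :, t : t + end : s]
            self.W.grad[:, :, t] += np.matmul(
                dy, xs.transpose(0, 2, 1)
            ).sum(axis=0)
            dxp[:, :, t : t + end : s] += np.matmul(
                self.W.value[:, :, t].T, dy
            )
        return dxp[:, :, p : p + L] if p else dxp


class ConvTranspose1d(Module):
    """1-D transposed convolution (fractionally strided upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.W = Parameter(_he_init(rng, (in_channels, out_channels, kernel), fan_in), "convT.W")
        self.b = Parameter(np.zeros(out_channels), "convT.b")
        self._cache: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def out_length(self, length: int) -> int:
        return (length - 1) * self.stride + self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, Lin = x.shape
        s, k = self.stride, self.kernel
        Lout = self.out_length(Lin)
        y = np.broadcast_to(
            self.b.value[None, :, None], (B, self.out_channels, Lout)
        ).copy()
        end = s * (Lin - 1) + 1
        for t in range(k):
            y[:, :, t : t + end : s] += np.matmul(self.W.value[:, :, t].T, x)
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        s, k = self.stride, self.kernel
        Lin = x.shape[2]
        self.b.grad += dy.sum(axis=(0, 2))
        dx = np.zeros_like(x)
        end = s * (Lin - 1) + 1
        for t in range(k):
            dys = dy[:, :, t : t + end : s]
            self.W.grad[:, :, t] += np.matmul(
                x, dys.transpose(0, 2, 1)
            ).sum(axis=0)
            dx += np.matmul(self.W.value[:, :, t], dys)
        return dx


class Dense(Module):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(_he_init(rng, (in_features, out_features), in_features), "dense.W")
        self.b = Parameter(np.zeros(out_features), "dense.b")
        self._cache: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm(Module):
    """Batch normalisation over (batch,) or (batch, length) per channel.

    Accepts ``(B, C, L)`` (normalises over B and L) or ``(B, C)``.
    Running statistics (momentum 0.9) are used at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def _axes(self, x: np.ndarray) -> tuple:
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x: np.ndarray) -> tuple:
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        self._cache = (xhat, inv_std, axes, shp)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shp = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self.training:
            return dy * (self.gamma.value * inv_std).reshape(shp)
        n = np.prod([dy.shape[a] for a in axes])
        dxhat = dy * self.gamma.value.reshape(shp)
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        )
        return term * inv_std.reshape(shp)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit  # overflow-safe logistic

        self._y = expit(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Clamp(Module):
    """Hard clip to [0, 1]; gradient passes only inside the interval."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < 1)
        return np.clip(x, 0.0, 1.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class AdaptiveMaxPool1d(Module):
    """Max-pool to a fixed number of output bins (PyTorch bin boundaries)."""

    def __init__(self, bins: int) -> None:
        if bins < 1:
            raise ValueError("bins must be >= 1")
        self.bins = bins

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        if self.bins > L:
            raise ValueError(f"cannot pool length {L} into {self.bins} bins")
        y = np.empty((B, C, self.bins))
        argmax = np.empty((B, C, self.bins), dtype=np.intp)
        for i in range(self.bins):
            lo = (i * L) // self.bins
            hi = -(-((i + 1) * L) // self.bins)  # ceil
            seg = x[:, :, lo:hi]
            idx = seg.argmax(axis=2)
            y[:, :, i] = np.take_along_axis(seg, idx[:, :, None], axis=2)[:, :, 0]
            argmax[:, :, i] = idx + lo
        self._cache = (x.shape, argmax)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, argmax = self._cache
        dx = np.zeros(shape)
        B, C, _ = shape
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        for i in range(self.bins):
            np.add.at(dx, (bi, ci, argmax[:, :, i]), dy[:, :, i])
        return dx


class Crop1d(Module):
    """Fixed center crop along the length axis."""

    def __init__(self, offset: int, length: int) -> None:
        self.offset = offset
        self.length = length

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_length = x.shape[2]
        return x[:, :, self.offset : self.offset + self.length]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pad_right = self._in_length - self.offset - self.length
        return np.pad(dy, ((0, 0), (0, 0), (self.offset, pad_right)))


class AddChannel(Module):
    """(B, L) -> (B, 1, L)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[:, 0, :]


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class SqueezeChannel(Module):
    """(B, 1, L) -> (B, L)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != 1:
            raise ValueError("expected a single channel")
        return x[:, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[:, None, :]


class PyramidPooling(Module):
    """Multi-bin pooled context branches concatenated with the feature map.

    Each branch max-pools the feature map to ``b`` bins, mixes channels with
    a length-1 convolution, applies ReLU, and upsamples back to the feature
    length with a transposed convolution; branch outputs are concatenated
    with the untouched feature map along the channel axis.
    """

    def __init__(
        self,
        channels: int,
        feature_length: int,
        bins: list[int],
        branch_channels: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.bins = list(bins)
        self.branch_channels = branch_channels
        self.branches: list[Sequential] = []
        for b in self.bins:
            if b > feature_length:
                raise ValueError(
                    f"pyramid bin {b} exceeds feature length {feature_length}"
                )
            stride = max(1, feature_length // b)
            kernel = feature_length - (b - 1) * stride
            self.branches.append(
                Sequential(
                    AdaptiveMaxPool1d(b),
                    Conv1d(channels, branch_channels, kernel=1, rng=rng),
                    ReLU(),
                    ConvTranspose1d(
                        branch_channels, branch_channels, kernel=kernel,
                        stride=stride, rng=rng,
                    ),
                )
            )
        self.channels = channels

    def modules(self) -> list[Module]:
        out: list[Module] = [self]
        for br in self.branches:
            out.extend(br.modules())
        return out

    def parameters(self) -> list[Parameter]:
        return [p for br in self.branches for p in br.parameters()]

    @property
    def out_channels(self) -> int:
        return self.channels + self.branch_channels * len(self.bins)

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [x] + [br.forward(x) for br in self.branches]
        return np.concatenate(outs, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = self.channels
        dx = dy[:, :c, :].copy()
        offset = c
        for br in self.branches:
            sl = dy[:, offset : offset + self.branch_channels, :]
            dx += br.backward(sl)
            offset += self.branch_channels
        return dx
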