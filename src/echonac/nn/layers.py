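"""Network building blocks: convolution, batch norm, dropout, SCSE, ASPP."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, maxpool2x, upsample2x


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list["Module"] = []
        self.training = True

    def add_param(self, array: np.ndarray) -> Tensor:
        p = Tensor(array, requires_grad=True)
        self._params.append(p)
        return p

    def add_module(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self._children:
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    """Same-padded conv with He-normal init and a bias term."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = self.add_param(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.b = self.add_param(np.zeros((1, out_ch, 1, 1), dtype=dtype))
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, dilation=self.dilation) + self.b


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = self.add_param(np.ones((1, channels, 1, 1), dtype=dtype))
        self.beta = self.add_param(np.zeros((1, channels, 1, 1), dtype=dtype))
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1, 1), dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0,1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by batch norm, dropout and ReLU."""

    def __init__(self, in_ch: int, out_ch: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.c1 = self.add_module(Conv2d(in_ch, out_ch, rng=rng))
        self.n1 = self.add_module(BatchNorm2d(out_ch))
        self.d1 = self.add_module(Dropout(dropout, rng=rng))
        self.c2 = self.add_module(Conv2d(out_ch, out_ch, rng=rng))
        self.n2 = self.add_module(BatchNorm2d(out_ch))
        self.d2 = self.add_module(Dropout(dropout, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        x = self.d1(self.n1(self.c1(x))).relu()
        return self.d2(self.n2(self.c2(x))).relu()


class SCSE(Module):
    """Concurrent spatial and channel squeeze-and-excitation attention.

    Channel branch: global average pool -> bottleneck MLP (1x1 convs) ->
    sigmoid gate per channel.  Spatial branch: 1x1 conv -> sigmoid gate per
    pixel.  Output is the sum of the two recalibrated maps.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = self.add_module(Conv2d(channels, hidden, kernel=1, rng=rng))
        self.fc2 = self.add_module(Conv2d(hidden, channels, kernel=1, rng=rng))
        self.spatial = self.add_module(Conv2d(channels, 1, kernel=1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3), keepdims=True)
        cgate = self.fc2(self.fc1(z).relu()).sigmoid()
        sgate = self.spatial(x).sigmoid()
        return x * cgate + x * sgate


class ASPP(Module):
    """Atrous spatial pyramid pooling over the bottleneck feature map.

    Parallel same-padded 3x3 convolutions at the given dilation rates (rate 1
    is implemented as a 1x1 convolution), plus a global-average-pooling branch
    broadcast back to the map, fused by a 1x1 projection with batch norm.
    """

    def __init__(self, channels: int, rates: tuple[int, ...] = (1, 6, 12, 18),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = []
        for r in self.rates:
            conv = Conv2d(channels, channels, kernel=1 if r == 1 else 3,
                          dilation=r, rng=rng)
            self.branches.append(self.add_module(conv))
        self.pool_conv = self.add_module(Conv2d(channels, channels, kernel=1, rng=rng))
        n_branch = len(self.rates) + 1
        self.project = self.add_module(
            Conv2d(channels * n_branch, channels, kernel=1, rng=rng))
        self.norm = self.add_module(BatchNorm2d(channels))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2], x.data.shape[3]
        feats = [b(x).relu() for b in self.branches]
        pooled = self.pool_conv(x.mean(axis=(2, 3), keepdims=True)).relu()
        feats.append(pooled.broadcast_hw(h, w))
        return self.norm(self.project(concat(feats, axis=1))).relu()


__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "Dropout", "ConvBlock", "SCSE", "ASPP",
    "Tensor", "concat", "maxpool2x", "upsample2x",
]
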