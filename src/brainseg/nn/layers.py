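"""Layer/module abstraction over the autodiff core."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def set_seed(seed: int):
    """Seed the default parameter-initialisation stream."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def _rng(rng):
    return _GLOBAL_RNG if rng is None else rng


def he_normal(shape, fan_in, rng=None) -> np.ndarray:
    return _rng(rng).normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def xavier_normal(shape, fan_in, fan_out, rng=None) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return _rng(rng).normal(0.0, std, size=shape).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: recursive parameter discovery, train/eval."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        def walk(value):
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)

        yield self
        for value in self.__dict__.values():
            yield from walk(value)

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
                elif isinstance(value, (list, tuple)):
                    params.extend(v for v in value if isinstance(v, Parameter))
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat state dict (parameters + batch-norm running stats)."""
        state = {}
        for i, mod in enumerate(self.modules()):
            for key, value in mod.__dict__.items():
                if isinstance(value, Parameter):
                    state[f"{i}.{key}"] = value.data
                elif isinstance(value, np.ndarray):
                    state[f"{i}.{key}"] = value
        return state

    def load_state(self, state: dict[str, np.ndarray]):
        own = self.named_state()
        if set(own) != set(state):
            raise ValueError("state dict does not match module structure")
        for i, mod in enumerate(self.modules()):
            for key, value in list(mod.__dict__.items()):
                name = f"{i}.{key}"
                if isinstance(value, Parameter):
                    value.data = state[name].astype(np.float32).copy()
                elif isinstance(value, np.ndarray):
                    setattr(mod, key, state[name].astype(value.dtype).copy())

    def train(self):
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self):
        for mod in self.modules():
            mod.training = False
        return self

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: str = "same", bias: bool = True, init: str = "he", rng=None):
        super().__init__()
        fan_in = kernel * kernel * in_ch
        if init == "he":
            w = he_normal((kernel, kernel, in_ch, out_ch), fan_in, rng)
        elif init == "xavier":
            w = xavier_normal((kernel, kernel, in_ch, out_ch), fan_in,
                              kernel * kernel * out_ch, rng)
        elif init == "zeros":
            w = np.zeros((kernel, kernel, in_ch, out_ch), dtype=np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, stride: int = 1,
                 bias: bool = True, rng=None):
        super().__init__()
        self.weight = Parameter(he_normal((kernel, kernel, channels),
                                          kernel * kernel, rng))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None
        self.stride = stride

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x):
        return F.maxpool2d(x, self.size)


class Upsample2x(Module):
    def __init__(self, mode: str = "bilinear"):
        super().__init__()
        if mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode

    def forward(self, x):
        if self.mode == "bilinear":
            return F.upsample_bilinear2x(x)
        return F.upsample_nearest2x(x)


class ConvBNAct(Module):
    """Convolution -> batch norm -> activation, the network's workhorse block."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, act: str = "relu", rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = {"relu": ReLU(), "relu6": ReLU6(), "none": Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class SeparableConvBlock(Module):
    """Depthwise 3x3 + pointwise 1x1, each followed by BN and activation.

    Used for feature fusion inside the bidirectional pyramid; costs
    C*k*k + C*C parameters against C*C*k*k for a full convolution.
    """

    def __init__(self, channels: int, kernel: int = 3, act: str = "relu", rng=None):
        super().__init__()
        self.depthwise = DepthwiseConv2d(channels, kernel, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.pointwise = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.act = {"relu": ReLU(), "relu6": ReLU6(), "none": Identity()}[act]

    def forward(self, x):
        x = self.act(self.bn1(self.depthwise(x)))
        return self.act(self.bn2(self.pointwise(x)))
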