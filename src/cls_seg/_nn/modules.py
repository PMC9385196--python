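"""Layer/module abstractions over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, linear, relu, sigmoid, silu

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "ConvBNAct",
           "Linear", "Sequential"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter registration and (de)serialization."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: p.data for k, p in self._params.items()}
        state.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            state.update(m.named_state(prefix + name + "."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = sorted(set(own) - set(state))
        if missing:
            raise KeyError(f"state dict missing keys: {missing}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=v.dtype)
            if arr.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {v.shape}")
            v[...] = arr

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, *, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.register_buffer("running_mean", np.zeros(num_ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_ch, dtype=np.float32))
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        C = x.data.shape[1]
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, C, 1, 1)) * ivstd.reshape(1, C, 1, 1)
        out = self.gamma.data.reshape(1, C, 1, 1) * xhat \
            + self.beta.data.reshape(1, C, 1, 1)
        gamma, beta, training = self.gamma, self.beta, self.training

        def backward(g, x=x, xhat=xhat, ivstd=ivstd, gamma=gamma, beta=beta,
                     training=training, C=C):
            iv = ivstd.reshape(1, C, 1, 1)
            ga = gamma.data.reshape(1, C, 1, 1)
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            if not training:
                x._accumulate(g * ga * iv)
                return
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gxhat = g * ga
            t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accumulate(iv / m * (m * gxhat - t1 - xhat * t2))

        return Tensor._result(out, (x, gamma, beta), backward)


_ACTS = {"relu": relu, "silu": silu, "sigmoid": sigmoid, None: lambda t: t}


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the standard CNN building block."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 dilation: int = 1, groups: int = 1, act: str | None = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        pad = dilation * (kernel - 1) // 2
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, padding=pad,
                           dilation=dilation, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self._act = _ACTS[act]

    def forward(self, x: Tensor) -> Tensor:
        return self._act(self.bn(self.conv(x)))


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)
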