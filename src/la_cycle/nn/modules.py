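"""Layer and optimizer primitives on top of the autograd tape."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    conv3d,
    conv_transpose3d,
    instance_norm,
    prelu,
    sigmoid,
    upsample_nearest,
)

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "PReLU",
    "Linear",
    "Sigmoid",
    "Tanh",
    "Adam",
]


class Module:
    """Minimal container: children and parameters discovered by attribute scan."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def named_modules(self, prefix=""):
        yield prefix, self
        for k, v in self.__dict__.items():
            name = f"{prefix}.{k}" if prefix else k
            if isinstance(v, Module):
                yield from v.named_modules(name)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{name}.{i}")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        state = {}
        for mname, mod in self.named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{mname}.{k}" if mname else k] = v.data.copy()
        return state

    def load_state_dict(self, state):
        for mname, mod in self.named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    key = f"{mname}.{k}" if mname else k
                    v.data[...] = state[key]

    def __call__(self, x):
        return self.forward(x)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int, a: float = 0.25):
    """He-normal for leaky/PReLU units: std = sqrt(2 / ((1 + a^2) fan_in))."""
    std = np.sqrt(2.0 / ((1.0 + a * a) * fan_in))
    return rng.normal(0.0, std, size=shape)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, pad=None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = cin * kernel ** 3
        self.weight = Tensor(kaiming_normal(rng, (cout, cin, kernel, kernel, kernel),
                                            fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose3d(Module):
    def __init__(self, cin, cout, stride=2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        fan_in = cin * stride ** 3
        self.weight = Tensor(kaiming_normal(rng, (cin, cout, stride, stride, stride),
                                            fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    def __init__(self, channels, eps=1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta, eps=self.eps)


class PReLU(Module):
    def __init__(self, channels, init=0.25):
        self.alpha = Tensor(np.full(channels, init), requires_grad=True)

    def forward(self, x):
        return prelu(x, self.alpha)


class Linear(Module):
    def __init__(self, nin, nout, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Tensor(kaiming_normal(rng, (nin, nout), nin, a=1.0),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Tanh(Module):
    def forward(self, x):
        from .autograd import Tensor as T
        out = T(np.tanh(x.data), x.requires_grad, (x,))

        def bwd():
            if x.requires_grad:
                x._accum(out.grad * (1.0 - out.data ** 2))

        out._backward = bwd
        return out


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


# re-exported for callers building custom graphs
upsample_nearest = upsample_nearest
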