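"""Neural-network layers on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Parameter,
    Tensor,
    batch_norm2d,
    conv2d,
    dropout,
    global_avg_pool,
    maxpool2d,
    upsample_nearest2x,
)


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation --------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running stats, in a fixed order."""
        out = []
        for m in self.modules():
            for k in sorted(m.__dict__):
                v = m.__dict__[k]
                if isinstance(v, Parameter):
                    out.append(v.data)
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    out.append(v)
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for m in self.modules():
            for k in sorted(m.__dict__):
                v = m.__dict__[k]
                if isinstance(v, Parameter):
                    v.data = np.asarray(next(it), dtype=np.float32).reshape(v.data.shape)
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    m.__dict__[k] = np.asarray(next(it), dtype=np.float64).reshape(v.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        # He-normal init, suited to the ReLU nonlinearities used throughout
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Dropout(Module):
    def __init__(self, p: float, *, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2x(x)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return global_avg_pool(x)


class ConvBNReLU(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Adam:
    """Adam with optional (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
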