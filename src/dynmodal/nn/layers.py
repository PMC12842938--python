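"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "CausalDepthwiseConv1d",
]


class Parameter(Tensor):
    """A tensor registered as a trainable weight."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    # traversal ---------------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        def walk(name, value):
            if isinstance(value, Parameter):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            yield from walk(f"{prefix}{name}", value)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _submodules(self):
        def walk(value):
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)

        for value in vars(self).values():
            yield from walk(value)

    def train(self, flag: bool = True):
        self.training = flag
        for m in self._submodules():
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)

    # persistence -------------------------------------------------------------

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask randomness comes from
    the generator passed at call time so whole-model runs stay seeded."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        # active only in training mode AND when a noise source is supplied
        # (hard/inference forwards pass no rng)
        if not self.training or self.p == 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class CausalDepthwiseConv1d(Module):
    """Depthwise 1-D convolution over the token axis with left padding, so the
    output at step t sees only steps <= t and length is preserved.

    Input shape (..., N, C); one kernel of length K per channel.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        limit = np.sqrt(1.0 / (channels * kernel))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(kernel, channels)))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        n = x.shape[-2]
        if k > 1:
            zeros = Tensor(np.zeros(x.shape[:-2] + (k - 1, x.shape[-1])))
            xp = concatenate([zeros, x], axis=-2)
        else:
            xp = x
        out = None
        for j in range(k):
            term = xp[..., j : j + n, :] * self.weight[j]
            out = term if out is None else out + term
        return out + self.bias
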