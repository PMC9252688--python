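"""Small module/layer system on top of :mod:`echoseg.autograd`.

Provides the ``Module`` base class (parameter traversal, train/eval mode,
state dicts) plus the two parameterised layers the segmentation network is
assembled from: ``Conv2d`` (stride 1, "same" padding, even kernels padded
top/left-heavy) and ``BatchNorm2d``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor

__all__ = ["Module", "ModuleList", "Conv2d", "BatchNorm2d"]


class Module:
    """Base class: attribute-walking parameter registry and mode switch."""

    _buffer_names: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- traversal -----------------------------------------------------------

    def named_members(self, prefix: str = "") -> Iterator[tuple[str, object]]:
        for name, value in vars(self).items():
            if name.startswith("_") or name == "training":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_members(prefix=full + ".")
        for name in self._buffer_names:
            yield f"{prefix}{name}", getattr(self, name)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for name, value in self.named_members():
            if isinstance(value, Parameter):
                yield name, value

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode ----------------------------------------------------------------

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, value in self.named_members():
            arr = value.data if isinstance(value, Parameter) else value
            out[name] = np.array(arr, copy=True)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_members())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name, value in own.items():
            new = np.asarray(state[name], dtype=np.float64)
            if isinstance(value, Parameter):
                if new.shape != value.data.shape:
                    raise ValueError(f"shape mismatch for {name}")
                value.data = new.copy()
            else:
                # buffer: find owner module and set attribute
                owner = self
                parts = name.split(".")
                for part in parts[:-1]:
                    owner = getattr(owner, part)
                setattr(owner, parts[-1], new.copy())


class ModuleList(Module):
    """An indexable container whose entries are registered as submodules."""

    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
        self._n = len(tuple(modules)) if not isinstance(modules, list) else len(modules)

    def append(self, module: Module) -> None:
        setattr(self, str(self._n), module)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, idx: int) -> Module:
        return getattr(self, str(idx % self._n if idx < 0 else idx))

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def named_members(self, prefix: str = ""):
        for i in range(self._n):
            yield from getattr(self, str(i)).named_members(prefix=f"{prefix}{i}.")

    def modules(self):
        yield self
        for i in range(self._n):
            yield from getattr(self, str(i)).modules()


class Conv2d(Module):
    """Stride-1 2-D convolution with "same" output size.

    Even kernels pad one pixel more on the top/left.  Weights are drawn by
    the caller-supplied initialiser (scaled Gaussian by default elsewhere);
    without an ``rng`` the layer starts at zero, which the tests rely on for
    hand-set weights.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        if rng is not None:
            from .optim import init_weights

            self.weight = Parameter(init_weights(shape, rng))
        else:
            self.weight = Parameter(np.zeros(shape))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)

    def named_members(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics and updates exponential
    running averages (biased variance, momentum 0.1); eval mode normalises
    by the running averages, so inference is deterministic and
    batch-size-independent.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones((1, channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight + self.bias
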