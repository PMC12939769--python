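"""Layer modules built on the autodiff primitives.

Modules own :class:`~blastoseg.nn.autodiff.Parameter` leaves, expose
``__call__(x, training)`` and recurse through ``parameters()`` /
``state_dict()`` for optimization and serialization.  Weight init is
He-uniform (bound ``sqrt(6 / fan_in)``) from a caller-supplied generator;
batch-norm starts at scale 1, shift 0.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ReLU", "Sequential"]


class Module:
    def submodules(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        out = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for _, m in self.submodules():
            out.extend(m.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                state[prefix + name] = v.data
            elif isinstance(v, np.ndarray):  # batch-norm running stats
                state[prefix + name] = v
        for name, m in self.submodules():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in list(vars(self).items()):
            if isinstance(v, Parameter):
                v.data = np.asarray(state[prefix + name], dtype=np.float32).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                arr = np.asarray(state[prefix + name], dtype=v.dtype).reshape(v.shape)
                v[...] = arr
        for name, m in self.submodules():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        raise NotImplementedError


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Grouped 2-D convolution (plain, point-wise, or strided)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"in/out channels ({in_channels}, {out_channels}) must be divisible by groups={groups}"
            )
        rng = rng or np.random.default_rng()
        k = kernel_size
        cg = in_channels // groups
        self.stride = stride
        self.groups = groups
        self.padding = k // 2
        self.weight = Parameter(_he_uniform(rng, (out_channels, cg, k, k), cg * k * k), decay=True)
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    """Stride-2 learnable upsampling that exactly doubles the spatial side."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.weight = Parameter(
            _he_uniform(rng, (in_channels, out_channels, k, k), in_channels * k * k),
            decay=True,
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=2, padding=1, output_padding=1)


class BatchNorm2d(Module):
    """Per-channel normalization with learnable scale/shift.

    With ``batch_stats_at_eval`` the layer normalizes by the current
    batch's statistics at inference too (instance-normalization
    semantics for batch size 1) instead of the running averages.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.batch_stats_at_eval = False

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training,
            self.momentum,
            self.eps,
            use_batch_stats=True if self.batch_stats_at_eval else None,
        )


class ReLU(Module):
    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return ad.relu(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.steps = list(modules)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        for m in self.steps:
            x = m(x, training)
        return x
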