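"""Layers and parameter containers built on the autodiff core."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from helixspec.nn.autodiff import Tensor, concat, constant, take_rows


class Module:
    """Base class: walks attributes to collect parameters recursively."""

    def parameters(self) -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{k}.{sub}", p

    def param_list(self) -> list[Tensor]:
        return [p for _, p in self.parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], float).copy()


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform init (or zeros)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Dense layers with ReLU between (none after the last)."""

    def __init__(self, sizes: Iterable[int], rng: np.random.Generator):
        sizes = list(sizes)
        self.layers = [
            Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Conv1d(Module):
    """Same-length 1D convolution over axis 0 of an (N, C) sequence.

    Implemented as zero row padding + window gather + one dense map, so the
    output length always equals the input length (kernel must be odd).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, zero_init: bool = False):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.c_in = c_in
        self.lin = Linear(kernel * c_in, c_out, rng, zero_init=zero_init)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        half = self.kernel // 2
        pad = constant(np.zeros((half, self.c_in)))
        xp = concat([pad, x, pad], axis=0)
        idx = np.arange(n)[:, None] + np.arange(self.kernel)[None, :]
        windows = take_rows(xp, idx)  # (N, k, C)
        return self.lin(windows.reshape(n, self.kernel * self.c_in))


def rbf_expand(d: np.ndarray, n_rbf: int, r_max: float) -> np.ndarray:
    """Gaussian radial basis of distances on (0, r_max]; plain ndarray.

    Centers are evenly spaced on (0, r_max]; the width equals the spacing so
    adjacent basis functions overlap at ~0.6.
    """
    d = np.asarray(d, float).reshape(-1, 1)
    centers = np.linspace(r_max / n_rbf, r_max, n_rbf).reshape(1, -1)
    width = r_max / n_rbf
    return np.exp(-((d - centers) ** 2) / (2.0 * width**2))
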