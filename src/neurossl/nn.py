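"""Layers, modules and optimizers built on the autodiff engine.

Contains the 3D convolution (stride 1, "same" padding, downsampling done by
average pooling so both directions of the convolution gradient reduce to the
same sliding-window primitive), GroupNorm / LayerNorm, domain-specific batch
normalization (DSBN), and a decoupled-weight-decay Adam optimizer with a
cosine learning-rate schedule.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, as_tensor, concatenate

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv3d",
    "GroupNorm",
    "LayerNorm",
    "DSBN",
    "avg_pool3d",
    "global_avg_pool3d",
    "l2_normalize",
    "AdamW",
    "cosine_lr",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, state dict, train mode."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{k}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{k}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlate x (B,C,D,H,W) with w (O,C,k,k,k), stride 1, same padding."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # B,C,D,H,W,k,k,k
    B, C, D, H, W = x.shape
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, D * H * W, C * k**3)
    out = cols @ w.reshape(w.shape[0], -1).T  # B, DHW, O
    return out.transpose(0, 2, 1).reshape(B, w.shape[0], D, H, W), cols


class Conv3d(Module):
    """3D convolution, kernel k, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        fan_in = c_in * k**3
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.k = k

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        w, b = self.weight, self.bias
        out_data, cols = _conv3d_raw(x.data, w.data)
        out_data = out_data + b.data[None, :, None, None, None]
        k = self.k

        def bw(g):
            B, O, D, H, W = g.shape
            g2 = g.reshape(B, O, D * H * W).transpose(0, 2, 1)  # B, DHW, O
            if w.requires_grad:
                gw = np.tensordot(g2, cols, axes=([0, 1], [0, 1]))  # O, C*k^3
                w._accumulate(gw.reshape(w.data.shape))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                # full correlation of g with the flipped kernel, channels swapped
                w_flip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                gx, _ = _conv3d_raw(g, w_flip)
                x._accumulate(gx)

        return Tensor._make(out_data, (x, w, b), bw)


def avg_pool3d(x, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    B, C, D, H, W = x.data.shape
    f = factor
    if D % f or H % f or W % f:
        raise ValueError("grid not divisible by pooling factor")
    r = x.data.reshape(B, C, D // f, f, H // f, f, W // f, f)
    out_data = r.mean(axis=(3, 5, 7))

    def bw(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(np.repeat(g, f, axis=2), f, axis=3), f, axis=4)
            x._accumulate(gx / f**3)

    return Tensor._make(out_data, (x,), bw)


def global_avg_pool3d(x) -> Tensor:
    x = as_tensor(x)
    return x.mean(axis=-1).mean(axis=-1).mean(axis=-1)


class GroupNorm(Module):
    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("channels must be divisible by groups")
        self.n_groups = n_groups
        self.eps = eps
        self.weight = Parameter(np.ones(n_channels))
        self.bias = Parameter(np.zeros(n_channels))

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        B, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.n_groups
        xg = x.reshape(B, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) * ((var + self.eps) ** -0.5)
        xn = xn.reshape((B, C) + spatial)
        shape = (1, C) + (1,) * len(spatial)
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.weight + self.bias


class DSBN(Module):
    """Domain-specific batch normalization.

    Separate affine parameters and running statistics per site; at train time
    each site's sub-batch is normalized by its own batch statistics, so
    site-specific intensity statistics never leak into the shared weights.
    """

    def __init__(self, n_channels: int, n_sites: int, eps: float = 1e-5, momentum: float = 0.1):
        self.n_sites = n_sites
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones((n_sites, n_channels)))
        self.bias = Parameter(np.zeros((n_sites, n_channels)))
        self.running_mean = np.zeros((n_sites, n_channels))
        self.running_var = np.ones((n_sites, n_channels))
        self.training = True

    def forward(self, x, sites) -> Tensor:
        x = as_tensor(x)
        sites = np.asarray(sites)
        if sites.min() < 0 or sites.max() >= self.n_sites:
            raise ValueError("site id outside fitted site set")
        B, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        pieces, order = [], []
        for s in np.unique(sites):
            idx = np.nonzero(sites == s)[0]
            xs = x[idx]
            if self.training:
                # reduce over batch and spatial axes via flattening per channel
                flat = xs.transpose((1, 0) + tuple(range(2, xs.ndim))).reshape(C, -1)
                mu = flat.mean(axis=1)
                var = ((flat - mu.reshape(C, 1)) ** 2).mean(axis=1)
                self.running_mean[s] = (1 - self.momentum) * self.running_mean[s] + self.momentum * mu.data
                self.running_var[s] = (1 - self.momentum) * self.running_var[s] + self.momentum * var.data
            else:
                mu = as_tensor(self.running_mean[s])
                var = as_tensor(self.running_var[s])
            shape = (1, C) + (1,) * len(spatial)
            xn = (xs - mu.reshape(shape)) * ((var.reshape(shape) + self.eps) ** -0.5)
            xn = xn * self.weight[int(s)].reshape(shape) + self.bias[int(s)].reshape(shape)
            pieces.append(xn)
            order.extend(idx.tolist())
        out = concatenate(pieces, axis=0)
        inv = np.argsort(order)
        return out[inv]


def l2_normalize(x, eps: float = 1e-12) -> Tensor:
    x = as_tensor(x)
    nrm = ((x**2).sum(axis=-1, keepdims=True) + eps) ** 0.5
    return x / nrm


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mh / (np.sqrt(vh) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, step: int, total_steps: int, min_frac: float = 0.01) -> float:
    """Cosine decay from base_lr to min_frac*base_lr over total_steps."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + np.cos(np.pi * frac)))
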