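"""Neural-network layers over the autodiff tensor: convolution, batch
normalization, nearest-neighbour resampling, and a module/parameter system
that partitions parameters into BN-affine vs everything else (the partition
the test-time adaptation relies on)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Parameter", "Module", "Conv2d", "BatchNorm2d", "ConvBNReLU",
    "conv2d", "upsample_to",
]


class Parameter(Tensor):
    """A trainable tensor.  ``bn_affine`` marks batch-norm scale/shift."""

    __slots__ = ("bn_affine",)

    def __init__(self, data, bn_affine: bool = False, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)
        self.bn_affine = bn_affine


class Module:
    """Minimal container: registers parameters and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._mods[key] = value
        object.__setattr__(self, key, value)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (prefix + k, p)
        for k, m in self._mods.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def bn_parameters(self):
        """Exactly the batch-norm affine parameters (gamma, beta per layer)."""
        return [p for _, p in self.named_parameters() if p.bn_affine]

    def non_bn_parameters(self):
        return [p for _, p in self.named_parameters() if not p.bn_affine]

    def modules(self):
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        state = {("param:" + k): p.data.copy() for k, p in self.named_parameters()}
        for name, m in self._walk_modules():
            if isinstance(m, BatchNorm2d):
                state[f"buffer:{name}running_mean"] = m.running_mean.copy()
                state[f"buffer:{name}running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, val in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.array(val, dtype=np.float64)
            else:
                for mname, m in self._walk_modules():
                    if isinstance(m, BatchNorm2d) and name.startswith(mname):
                        setattr(m, name[len(mname):], np.array(val, dtype=np.float64))

    def _walk_modules(self, prefix: str = ""):
        yield (prefix, self)
        for k, m in self._mods.items():
            yield from m._walk_modules(prefix + k + ".")


# --------------------------------------------------------------------- conv
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * ho:stride,
                                 j:j + stride * wo:stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:hp - pad, pad:wp - pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (NCHW); weight is (C_out, C_in, kh, kw)."""
    cout, cin, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    val = np.matmul(wmat[None], cols).reshape(x.shape[0], cout, ho, wo)
    if bias is not None:
        val = val + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(val, parents, None)

    def bwd(g):
        g = np.asarray(g)
        gmat = g.reshape(x.shape[0], cout, ho * wo)
        if weight.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gmat)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding))
    out._backward = bwd
    return out


def upsample_to(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resampling to an exact (H, W)."""
    n, c, h, w = x.shape
    ho, wo = size
    ri = (np.arange(ho) * h) // ho
    ci = (np.arange(wo) * w) // wo
    out = Tensor._make(x.data[:, :, ri][:, :, :, ci], (x,), None)

    def bwd(g):
        g = np.asarray(g)
        full = np.zeros_like(x.data)
        # scatter-add along rows then columns
        tmp = np.zeros((n, c, ho, w), dtype=g.dtype)
        np.add.at(tmp, (slice(None), slice(None), slice(None), ci), g)
        np.add.at(full, (slice(None), slice(None), ri), tmp)
        x._accum(full)
    out._backward = bwd
    return out


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization with affine scale/shift.

    Training mode normalizes with batch statistics (and updates the running
    estimates); eval mode uses the running estimates.  ``recalibrate`` resets
    the running statistics directly from a batch, which is how adaptation
    re-estimates the normalization statistics from target-domain data.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), bn_affine=True)
        self.beta = Parameter(np.zeros(channels), bn_affine=True)
        object.__setattr__(self, "running_mean", np.zeros(channels))
        object.__setattr__(self, "running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b

    def recalibrate(self, x_data: np.ndarray):
        """Set running statistics to the statistics of a (target) batch."""
        self.running_mean = x_data.mean(axis=(0, 2, 3))
        self.running_var = x_data.var(axis=(0, 2, 3))


class ConvBNReLU(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, *, rng: np.random.Generator):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.conv = Conv2d(cin, cout, k, stride, padding, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
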