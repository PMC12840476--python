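"""Neural building blocks: 3D convolution, pooling, attention, dropout.

Layout convention is channels-last: volumetric activations are
``(batch, D, H, W, C)`` and token stacks are ``(batch, windows, tokens, C)``.
Weights are float32; initialisation draws from a caller-supplied
``numpy.random.Generator`` so whole networks are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from .autograd import Tensor, concatenate


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; parameter discovery walks attributes recursively."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.astype(np.float32).copy()

    def set_stochastic(self, flag: bool) -> None:
        """Enable/disable dropout sampling everywhere in the module tree."""

        def walk(obj):
            if isinstance(obj, Dropout):
                obj.active = flag
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)


def _triple(v) -> tuple[int, int, int]:
    return (v, v, v) if isinstance(v, int) else tuple(v)


def _im2col(xp: np.ndarray, kernel, stride) -> np.ndarray:
    """Patch matrix in kernel-major order: (B, Do, Ho, Wo, k^3 * C).

    Built from k^3 block slice-copies (contiguous inner runs), which is
    far cheaper on one core than gathering a strided window view.
    """
    kd, kh, kw = kernel
    sd, sh, sw = stride
    B, Dp, Hp, Wp, C = xp.shape
    Do = (Dp - kd) // sd + 1
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    cols = np.empty((B, Do, Ho, Wo, kd * kh * kw, C), dtype=xp.dtype)
    i = 0
    for a in range(kd):
        for b in range(kh):
            for c in range(kw):
                cols[..., i, :] = xp[
                    :, a : a + Do * sd : sd, b : b + Ho * sh : sh,
                    c : c + Wo * sw : sw, :,
                ]
                i += 1
    return cols.reshape(B, Do, Ho, Wo, -1)


class Conv3d(Module):
    """Channels-last 3D convolution with symmetric zero padding.

    Weight layout is kernel-major: rows of ``weight`` run over
    (kd, kh, kw, cin) in that order.
    """

    def __init__(self, cin, cout, kernel=3, stride=1, padding="same", *, rng):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if padding == "same":
            self.padding = tuple(k // 2 for k in self.kernel)
        else:
            self.padding = _triple(padding)
        fan_in = cin * int(np.prod(self.kernel))
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.cin, self.cout = cin, cout

    def __call__(self, x: Tensor) -> Tensor:
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
        cols = _im2col(xp, self.kernel, self.stride)
        B, Do, Ho, Wo = cols.shape[:4]
        out_data = cols @ self.weight.data + self.bias.data
        weight, bias = self.weight, self.bias
        xshape, pad, stride, kernel = x.shape, self.padding, self.stride, self.kernel

        def bwd(g):
            if weight.requires_grad:
                gw = cols.reshape(-1, cols.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                weight._accum(gw)
                bias._accum(g.sum(axis=(0, 1, 2, 3)))
            if x.requires_grad:
                pd_, ph_, pw_ = pad
                cin, cout = xshape[-1], g.shape[-1]
                if stride == (1, 1, 1):
                    # input gradient = full correlation with the spatially
                    # flipped, channel-transposed kernel
                    w6 = weight.data.reshape(kd, kh, kw, cin, cout)
                    wb = np.ascontiguousarray(
                        w6[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
                    ).reshape(kd * kh * kw * cout, cin)
                    gp = np.pad(
                        g,
                        ((0, 0), (kd - 1, kd - 1), (kh - 1, kh - 1),
                         (kw - 1, kw - 1), (0, 0)),
                    )
                    gcols = _im2col(gp, kernel, (1, 1, 1))
                    dxp = gcols @ wb
                    dx = dxp[
                        :, pd_ : pd_ + xshape[1], ph_ : ph_ + xshape[2],
                        pw_ : pw_ + xshape[3], :,
                    ]
                else:
                    dcols = (g @ weight.data.T).reshape(
                        B, Do, Ho, Wo, kd * kh * kw, cin
                    )
                    dxp = np.zeros_like(xp)
                    i = 0
                    for a in range(kd):
                        for b in range(kh):
                            for c in range(kw):
                                dxp[
                                    :, a : a + Do * sd : sd,
                                    b : b + Ho * sh : sh,
                                    c : c + Wo * sw : sw, :,
                                ] += dcols[..., i, :]
                                i += 1
                    dx = dxp[
                        :, pd_ : pd_ + xshape[1], ph_ : ph_ + xshape[2],
                        pw_ : pw_ + xshape[3], :,
                    ]
                x._accum(dx)

        return Tensor._make(out_data, (x, weight, bias), bwd)


class ConvTranspose3d2x(Module):
    """2x2x2 stride-2 up-convolution, expressed as a per-voxel linear map."""

    def __init__(self, cin, cout, *, rng):
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout * 8)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        B, D, H, W, _ = x.shape
        y = x @ self.weight  # (B, D, H, W, cout*8)
        y = y.reshape(B, D, H, W, 2, 2, 2, self.cout)
        y = y.transpose((0, 1, 4, 2, 5, 3, 6, 7))
        y = y.reshape(B, 2 * D, 2 * H, 2 * W, self.cout)
        return y + self.bias


class MaxPool3d2(Module):
    """2x2x2 max pooling; spatial dims must be even."""

    def __call__(self, x: Tensor) -> Tensor:
        B, D, H, W, C = x.shape
        blocks = x.data.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        out_data = blocks.max(axis=(2, 4, 6))
        mask = blocks == out_data[:, :, None, :, None, :, None, :]
        # guard against ties double-routing gradient
        norm = mask.sum(axis=(2, 4, 6), keepdims=True)

        def bwd(g):
            gb = (mask / norm) * g[:, :, None, :, None, :, None, :]
            x._accum(gb.reshape(B, D, H, W, C).astype(np.float32))

        return Tensor._make(out_data, (x,), bwd)


class Linear(Module):
    def __init__(self, cin, cout, *, rng):
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; stays active at inference for MC sampling when
    ``active`` is left on (Monte Carlo dropout)."""

    def __init__(self, p: float, *, rng):
        self.p = float(p)
        self.rng = rng
        self.active = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.active or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep

        def bwd(g):
            x._accum(g * mask)

        return Tensor._make(x.data * mask, (x,), bwd)


class WindowAttention(Module):
    """Multi-head self-attention within fixed token windows.

    Input ``(B, n_windows, T, C)``; attention never crosses windows.
    """

    def __init__(self, dim, n_heads, *, rng):
        assert dim % n_heads == 0
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, nW, T, C = x.shape
        h, dh = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(B, nW, T, 3, h, dh)
        qkv = qkv.transpose((3, 0, 1, 4, 2, 5))  # (3, B, nW, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose((0, 1, 2, 4, 3))) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, nW, h, T, dh)
        out = out.transpose((0, 1, 3, 2, 4)).reshape(B, nW, T, C)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm windowed attention + MLP block."""

    def __init__(self, dim, n_heads, *, rng, mlp_ratio: int = 2):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng=rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        h = self.fc2(self.fc1(self.norm2(x)).relu())
        return x + h


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""
    B, D, H, W, C = x.shape
    ones = Tensor(np.ones((1, 1, 2, 1, 2, 1, 2, 1), dtype=np.float32))
    y = x.reshape(B, D, 1, H, 1, W, 1, C) * ones
    return y.reshape(B, 2 * D, 2 * H, 2 * W, C)


concat = concatenate
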