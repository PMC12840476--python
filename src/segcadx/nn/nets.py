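"""Network architectures: residual 3D U-Net, 2.5D refinement head, and the
dual-stream (dense-convolutional + windowed self-attention) malignancy
classifier with late radiomics fusion.

All models are deliberately small: they are trained on CPU against
synthetic phantoms, so widths/depths default to the smallest configuration
that preserves each architectural idea (residual skips, encoder/decoder
symmetry, dense connectivity, hierarchical windowed attention).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate
from .layers import (
    Conv3d,
    ConvTranspose3d2x,
    Dropout,
    Linear,
    MaxPool3d2,
    Module,
    TransformerBlock,
)


class ResBlock3d(Module):
    """Two 3x3x3 convolutions with an identity (or 1x1x1-projected) skip."""

    def __init__(self, cin, cout, *, rng):
        self.conv1 = Conv3d(cin, cout, 3, rng=rng)
        self.conv2 = Conv3d(cout, cout, 3, rng=rng)
        self.proj = Conv3d(cin, cout, 1, rng=rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class ResUNet3d(Module):
    """Residual 3D U-Net with 2x2x2 max-pooled encoder, 2x2x2 up-convolved
    decoder, skip connections, and optional deep supervision.

    ``forward`` maps ``(B, D, H, W, 1)`` to a same-shape logit map plus a
    list of auxiliary coarser logit maps when deep supervision is enabled.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8,
                 deep_supervision: bool = False, in_channels: int = 1, *, rng):
        self.depth = depth
        self.deep_supervision = deep_supervision
        chans = [base_channels * 2**l for l in range(depth + 1)]
        self.encoders = []
        cin = in_channels
        for l in range(depth):
            self.encoders.append(ResBlock3d(cin, chans[l], rng=rng))
            cin = chans[l]
        self.pool = MaxPool3d2()
        self.bottleneck = ResBlock3d(chans[depth - 1], chans[depth], rng=rng)
        self.upconvs = []
        self.decoders = []
        self.aux_heads = []
        for l in reversed(range(depth)):
            self.upconvs.append(ConvTranspose3d2x(chans[l + 1], chans[l], rng=rng))
            self.decoders.append(ResBlock3d(2 * chans[l], chans[l], rng=rng))
            if deep_supervision and l > 0:
                self.aux_heads.append(Conv3d(chans[l], 1, 1, rng=rng))
        self.out_head = Conv3d(chans[0], 1, 1, rng=rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = self.pool(h)
        h = self.bottleneck(h)
        aux = []
        for i, (up, dec) in enumerate(zip(self.upconvs, self.decoders)):
            h = up(h)
            h = dec(concatenate([h, skips[-(i + 1)]], axis=-1))
            if self.deep_supervision and i < len(self.aux_heads):
                aux.append(self.aux_heads[i](h))
        return self.out_head(h), aux


class RefineHead2p5D(Module):
    """Lightweight 2.5D refinement head.

    Consumes a stack of ``k`` adjacent axial slices as channels,
    ``(B, 1, S, S, k)``, and predicts two-class logits (nodule vs.
    non-nodule) together with regression targets
    ``(radius_mm, off_x, off_y, off_z)`` (offsets in voxels).
    """

    def __init__(self, k_slices: int = 5, width: int = 8, *, rng):
        self.conv1 = Conv3d(k_slices, width, (1, 3, 3), stride=(1, 2, 2), rng=rng)
        self.conv2 = Conv3d(width, 2 * width, (1, 3, 3), stride=(1, 2, 2), rng=rng)
        self.conv3 = Conv3d(2 * width, 2 * width, (1, 3, 3), stride=(1, 2, 2), rng=rng)
        self.cls_head = Linear(2 * width, 2, rng=rng)
        self.reg_head = Linear(2 * width, 4, rng=rng)

    def __call__(self, slabs: Tensor) -> tuple[Tensor, Tensor]:
        h = self.conv1(slabs).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        h = h.mean(axis=(1, 2, 3))  # global average pool -> (B, 2*width)
        return self.cls_head(h), self.reg_head(h)


class DenseBlock3d(Module):
    """Densely connected 3D convolutions: each layer sees all previous maps."""

    def __init__(self, cin, growth: int, n_layers: int, *, rng):
        self.layers = []
        c = cin
        for _ in range(n_layers):
            self.layers.append(Conv3d(c, growth, 3, rng=rng))
            c += growth
        self.cout = c

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.layers:
            x = concatenate([x, conv(x).relu()], axis=-1)
        return x


def _window_partition(tokens: Tensor, win: int) -> tuple[Tensor, tuple]:
    B, D, H, W, C = tokens.shape
    nd, nh, nw = D // win, H // win, W // win
    t = tokens.reshape(B, nd, win, nh, win, nw, win, C)
    t = t.transpose((0, 1, 3, 5, 2, 4, 6, 7))
    return t.reshape(B, nd * nh * nw, win**3, C), (nd, nh, nw)


def _window_merge(x: Tensor, grid: tuple, win: int) -> Tensor:
    nd, nh, nw = grid
    B = x.shape[0]
    C = x.shape[-1]
    t = x.reshape(B, nd, nh, nw, win, win, win, C)
    t = t.transpose((0, 1, 4, 2, 5, 3, 6, 7))
    return t.reshape(B, nd * win, nh * win, nw * win, C)


class AttnStream3d(Module):
    """Two-stage hierarchical windowed self-attention encoder on 3D tokens.

    Stage 1: 4 mm patch embedding then windowed attention (4^3 windows);
    stage 2: 2x patch merging then attention over the coarser grid.
    """

    def __init__(self, dim: int = 16, n_heads: int = 2, window: int = 4,
                 patch: int = 4, *, rng):
        self.window = window
        self.embed = Conv3d(1, dim, patch, stride=patch, padding=0, rng=rng)
        self.block1 = TransformerBlock(dim, n_heads, rng=rng)
        self.merge = Linear(8 * dim, 2 * dim, rng=rng)
        self.block2 = TransformerBlock(2 * dim, n_heads, rng=rng)
        self.out_dim = 2 * dim

    def __call__(self, x: Tensor) -> Tensor:
        tok = self.embed(x)  # (B, g, g, g, dim)
        win = min(self.window, tok.shape[1])
        w, grid = _window_partition(tok, win)
        tok = _window_merge(self.block1(w), grid, win)
        B, D, H, W, C = tok.shape
        m = tok.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        m = m.transpose((0, 1, 3, 5, 2, 4, 6, 7)).reshape(
            B, (D // 2) * (H // 2) * (W // 2), 8 * C
        )
        m = self.merge(m)  # coarse tokens, one global window
        m = self.block2(m.reshape(B, 1, m.shape[1], m.shape[2]))
        return m.mean(axis=(1, 2))  # (B, 2*dim)


class HybridClassifier(Module):
    """Dual-stream malignancy classifier with late radiomics fusion.

    Stream A: densely connected 3D convolutional encoder (local texture).
    Stream B: hierarchical windowed self-attention encoder (global context).
    Deep embeddings are concatenated with the radiomics vector,
    ``f = [z || r]``, and passed through an MLP trunk with Monte Carlo
    dropout to a sigmoid malignancy head plus one regression head per
    auxiliary attribute (spiculation, lobulation, subtlety in [0, 1]).

    Either stream and the radiomics input can be disabled to realise the
    single-stream / no-radiomics ablation arms.
    """

    def __init__(self, n_radiomics: int, use_dense: bool = True,
                 use_attn: bool = True, use_radiomics: bool = True,
                 dropout: float = 0.3, attn_dim: int = 8, *, rng):
        if not (use_dense or use_attn):
            raise ValueError("at least one stream must be enabled")
        self.use_dense, self.use_attn = use_dense, use_attn
        self.use_radiomics = use_radiomics
        fused = 0
        if use_dense:
            self.stem = Conv3d(1, 8, 3, stride=2, padding=1, rng=rng)
            self.dense1 = DenseBlock3d(8, growth=4, n_layers=2, rng=rng)
            self.compress = Conv3d(self.dense1.cout, 8, 1, rng=rng)
            self.pool = MaxPool3d2()
            self.dense2 = DenseBlock3d(8, growth=4, n_layers=2, rng=rng)
            fused += self.dense2.cout
        if use_attn:
            self.attn_stream = AttnStream3d(dim=attn_dim, rng=rng)
            fused += self.attn_stream.out_dim
        # dropout on the deep embedding z (not on the handcrafted r): the
        # learned features are the high-variance part of the fusion
        self.drop_deep = Dropout(dropout, rng=np.random.default_rng(1))
        if use_radiomics:
            fused += n_radiomics
        self.trunk1 = Linear(fused, 32, rng=rng)
        self.drop = Dropout(dropout, rng=np.random.default_rng(0))
        self.mal_head = Linear(32, 1, rng=rng)
        self.attr_head = Linear(32, 3, rng=rng)

    def __call__(self, cube: Tensor, radiomics: Tensor) -> tuple[Tensor, Tensor]:
        """Return (malignancy logit (B,), attribute predictions (B, 3))."""
        parts = []
        if self.use_dense:
            h = self.stem(cube).relu()
            h = self.compress(self.dense1(h)).relu()
            h = self.dense2(self.pool(h))
            parts.append(h.mean(axis=(1, 2, 3)))
        if self.use_attn:
            parts.append(self.attn_stream(cube))
        z = self.drop_deep(concatenate(parts, axis=-1) if len(parts) > 1 else parts[0])
        f = concatenate([z, radiomics], axis=-1) if self.use_radiomics else z
        h = self.drop(self.trunk1(f).relu())
        logit = self.mal_head(h).reshape(cube.shape[0])
        attrs = self.attr_head(h)
        return logit, attrs
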