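"""Voxelwise nodule segmentation: residual 3D U-Net, composite losses,
patch sampling, mask postprocessing, overlap metrics, and training.

The segmentation loss is one configurable composite

    L = L_Dice + lambda_bce * L_BCE + alpha_focal * L_Focal

with foreground voxels up-weighted ``fg_weight``:1 (default 3:1) in the
Dice and focal terms.  Setting ``lambda_bce = 0`` or ``alpha_focal = 0``
recovers either pure variant of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import AdamW, ResUNet3d, Tensor, cosine_warm_restarts, no_grad
from .phantom import PhantomScan
from .preprocess import hu_window_normalize
from .volume import Volume

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_P_CLAMP = 1e-6


@dataclass
class SegConfig:
    depth: int = 2
    base_channels: int = 8
    deep_supervision: bool = False
    patch_size: int = 64  # voxels per side
    lambda_bce: float = 1.0  # BCE weight
    alpha_focal: float = 1.0  # focal weight
    gamma_focal: float = 2.0  # focusing exponent
    fg_weight: float = 3.0  # foreground voxel weight

    def __post_init__(self) -> None:
        if min(self.lambda_bce, self.alpha_focal, self.gamma_focal) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.fg_weight < 1:
            raise ValueError("fg_weight must be >= 1")


@dataclass
class SegPrediction:
    prob_map: Volume
    aux_maps: list[Volume] = field(default_factory=list)


def build_residual_unet3d(cfg: SegConfig, seed: int = 0) -> ResUNet3d:
    if cfg.patch_size % (2**cfg.depth) != 0:
        raise ValueError(
            f"patch_size {cfg.patch_size} not divisible by 2^depth={2**cfg.depth}"
        )
    return ResUNet3d(
        depth=cfg.depth,
        base_channels=cfg.base_channels,
        deep_supervision=cfg.deep_supervision,
        rng=np.random.default_rng(seed),
    )


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def dice_coefficient(P: np.ndarray, G: np.ndarray, eps: float = 1e-5) -> float:
    """Soft Dice similarity 2*sum(P*G) / (sum(P^2) + sum(G^2)), smoothed
    by ``eps`` in numerator and denominator (defines the empty/empty case
    as 1)."""
    P = np.asarray(P, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    num = 2.0 * (P * G).sum() + eps
    den = (P * P).sum() + (G * G).sum() + eps
    return float(num / den)


def dice_loss(P: np.ndarray, G: np.ndarray, eps: float = 1e-5) -> float:
    return 1.0 - dice_coefficient(P, G, eps)


def _seg_loss_tensor(
    P: Tensor, G: np.ndarray, cfg: SegConfig, eps: float = 1e-5,
    batched: bool = False,
) -> Tensor:
    """Composite loss on a probability Tensor (differentiable path).

    With ``batched=True`` the Dice term is computed per sample (axis 0)
    and averaged, so easy empty patches cannot swamp the overlap signal.
    """
    G = np.asarray(G, dtype=np.float32)
    w = np.where(G > 0.5, cfg.fg_weight, 1.0).astype(np.float32)
    Pc = P * (1.0 - 2.0 * _P_CLAMP) + _P_CLAMP
    # weighted soft Dice
    if batched:
        axes = tuple(range(1, G.ndim))
        num = (Pc * Tensor(G * w)).sum(axis=axes) * 2.0 + eps
        den = (
            (Pc * Pc * Tensor(w)).sum(axis=axes)
            + Tensor((G * G * w).sum(axis=axes))
            + eps
        )
        loss = 1.0 - (num / den).mean()
    else:
        num = (Pc * Tensor(G * w)).sum() * 2.0 + eps
        den = (Pc * Pc * Tensor(w)).sum() + float((G * G * w).sum()) + eps
        loss = 1.0 - num / den
    if cfg.lambda_bce > 0:
        bce = -(Tensor(G) * Pc.log() + Tensor(1.0 - G) * (1.0 - Pc).log()).mean()
        loss = loss + cfg.lambda_bce * bce
    if cfg.alpha_focal > 0:
        # p_t = P where G=1 else 1-P; weighted focal term
        pt = Pc * Tensor(G) + (1.0 - Pc) * Tensor(1.0 - G)
        focal = -(Tensor(w) * (1.0 - pt).pow(cfg.gamma_focal) * pt.log()).mean()
        loss = loss + cfg.alpha_focal * focal
    return loss


def seg_loss(P: np.ndarray, G: np.ndarray, cfg: SegConfig | None = None, eps: float = 1e-5) -> float:
    """Composite segmentation loss (Dice + weighted BCE + weighted focal)."""
    cfg = cfg or SegConfig()
    return float(_seg_loss_tensor(Tensor(np.asarray(P, dtype=np.float32)), G, cfg, eps).data)


def focal_term(p_t: float, gamma: float = 2.0, w: float = 1.0) -> float:
    """Single-voxel focal contribution -w * (1 - p_t)^gamma * log(p_t)."""
    return float(-w * (1.0 - p_t) ** gamma * np.log(p_t))


# ----------------------------------------------------------------------
# patch sampling (2:1 negative:positive per scan)
# ----------------------------------------------------------------------

def _extract_patch(data: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    """Crop a cubic patch, zero-padded at the borders."""
    half = size // 2
    lo = center - half
    hi = lo + size
    pad_lo = np.maximum(-lo, 0)
    pad_hi = np.maximum(hi - np.array(data.shape), 0)
    src = tuple(
        slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, data.shape)
    )
    patch = data[src]
    if pad_lo.any() or pad_hi.any():
        patch = np.pad(patch, list(zip(pad_lo, pad_hi)))
    return patch


def sample_patches(scan: PhantomScan, cfg: SegConfig, seed: int = 0) -> list[dict]:
    """Training patches for one scan: one positive patch per annotated
    nodule (jittered around its centre) and exactly twice as many
    nodule-free negatives from lung parenchyma.

    Nodule-free scans contribute no patches.  Returns dicts with keys
    ``image`` (windowed [0,1] intensities), ``mask`` (binary nodule mask),
    ``positive``.
    """
    if not scan.lung_mask_gt.data.any():
        raise ValueError(f"scan {scan.series_id} has no lung voxels")
    rng = np.random.default_rng(seed)
    # windowed + lung-masked, matching the representation used at inference
    img = np.where(
        scan.lung_mask_gt.data, hu_window_normalize(scan.volume).data, 0.0
    ).astype(np.float32)
    nodmask = scan.nodule_mask_gt.data > 0
    vol = scan.volume
    size = cfg.patch_size
    patches: list[dict] = []
    for n in scan.nodules:
        center = np.round(vol.world_to_voxel(n.center_mm)).astype(int)
        jitter = rng.integers(-4, 5, size=3)
        c = np.clip(center + jitter, 0, np.array(vol.shape) - 1)
        patches.append(
            {
                "image": _extract_patch(img, c, size).astype(np.float32),
                "mask": _extract_patch(nodmask.astype(np.float32), c, size),
                "positive": True,
            }
        )
    n_pos = len(patches)
    lung_idx = np.argwhere(scan.lung_mask_gt.data)
    negatives = 0
    attempts = 0
    while negatives < 2 * n_pos and attempts < 200 * max(2 * n_pos, 1):
        attempts += 1
        c = lung_idx[rng.integers(len(lung_idx))]
        m = _extract_patch(nodmask.astype(np.float32), c, size)
        if m.any():
            continue
        patches.append(
            {
                "image": _extract_patch(img, c, size).astype(np.float32),
                "mask": m,
                "positive": False,
            }
        )
        negatives += 1
    return patches


# ----------------------------------------------------------------------
# mask postprocessing and metrics
# ----------------------------------------------------------------------

def equivalent_diameter_mm(n_voxels: int, spacing_mm) -> float:
    """Diameter of the sphere with the same volume as ``n_voxels`` voxels."""
    voxvol = float(np.prod(spacing_mm))
    return 2.0 * (3.0 * n_voxels * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)


def postprocess_nodule_mask(
    prob: Volume, thr: float = 0.35, min_diameter_mm: float = 5.0
) -> Volume:
    """Threshold at ``thr``, drop 26-connected components whose
    equivalent-sphere diameter is below ``min_diameter_mm``, then apply
    morphological closing (1-voxel ball)."""
    binary = prob.data >= thr
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n:
        counts = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        for lab in range(1, n + 1):
            keep[lab] = (
                equivalent_diameter_mm(counts[lab], prob.spacing_mm)
                >= min_diameter_mm
            )
        binary = keep[labels]
        if binary.any():
            binary = ndimage.binary_closing(
                binary, structure=ndimage.generate_binary_structure(3, 1)
            )
    return prob.copy_with(binary)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    return mask & ~eroded


def seg_metrics(pred: Volume, gt: Volume) -> dict:
    """Binary-mask overlap metrics: Dice, IoU, and HD95 (mm).

    Empty/empty is defined as perfect agreement (dice=1, iou=1, hd95=0);
    one-sided emptiness yields dice=0, iou=0, hd95=inf.
    """
    p = pred.data.astype(bool)
    g = gt.data.astype(bool)
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    if not p.any() and not g.any():
        return {"dice": 1.0, "iou": 1.0, "hd95_mm": 0.0}
    if not p.any() or not g.any():
        return {"dice": 0.0, "iou": 0.0, "hd95_mm": float("inf")}
    inter = (p & g).sum()
    dice = 2.0 * inter / (p.sum() + g.sum())
    iou = inter / (p | g).sum()
    sp, sg = _surface_voxels(p), _surface_voxels(g)
    spacing = pred.spacing_mm
    dt_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    dists = np.concatenate([dt_g[sp], dt_p[sg]])
    return {
        "dice": float(dice),
        "iou": float(iou),
        "hd95_mm": float(np.percentile(dists, 95)),
    }


# ----------------------------------------------------------------------
# training and inference
# ----------------------------------------------------------------------

def _forward_loss(model: ResUNet3d, imgs: np.ndarray, masks: np.ndarray, cfg: SegConfig) -> Tensor:
    x = Tensor(imgs[..., None])
    logits, aux = model(x)
    P = logits.reshape(logits.shape[:-1]).sigmoid()
    # smoothing 1.0 during training keeps per-sample Dice well-behaved on
    # nodule-free patches (empty/empty -> ~1 once the map is near zero)
    loss = _seg_loss_tensor(P, masks, cfg, eps=1.0, batched=True)
    weight = 0.5
    for a in aux:  # deep supervision at coarser decoder levels
        factor = masks.shape[1] // a.shape[1]
        g = masks.reshape(
            masks.shape[0],
            a.shape[1], factor, a.shape[2], factor, a.shape[3], factor,
        ).max(axis=(2, 4, 6))
        Pa = a.reshape(a.shape[:-1]).sigmoid()
        loss = loss + weight * _seg_loss_tensor(Pa, g, cfg, eps=1.0, batched=True)
        weight *= 0.5
    return loss


def train_segmentation(
    patches: list[dict],
    cfg: SegConfig,
    seed: int = 0,
    n_steps: int = 300,
    batch_size: int = 4,
    lr: float = 3e-3,
    val_patches: list[dict] | None = None,
    eval_every: int = 25,
) -> tuple[ResUNet3d, pd.DataFrame]:
    """Train the residual U-Net with AdamW + cosine warm restarts.

    Keeps the best-validation-Dice parameters; returns (model, history).
    Raises on NaN loss (divergence).
    """
    if not any(p["positive"] for p in patches) or not any(
        not p["positive"] for p in patches
    ):
        raise ValueError("training set must contain positive and negative patches")
    rng = np.random.default_rng(seed)
    model = build_residual_unet3d(cfg, seed=seed)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-5)
    if val_patches is None:  # stratified split so both pools keep positives
        pos = [p for p in patches if p["positive"]]
        neg = [p for p in patches if not p["positive"]]
        rng.shuffle(pos)
        rng.shuffle(neg)
        n_vp = max(1, len(pos) // 5) if len(pos) > 1 else 0
        n_vn = max(1, len(neg) // 5) if len(neg) > 1 else 0
        val_patches = pos[:n_vp] + neg[:n_vn]
        patches = pos[n_vp:] + neg[n_vn:]
    history = []
    best_dice, best_state = -1.0, model.state_dict()
    pos_pool = [p for p in patches if p["positive"]]
    neg_pool = [p for p in patches if not p["positive"]]
    n_pos_batch = max(1, batch_size // 3)  # stratified: keep ~1:2 in-batch
    for step in range(n_steps):
        batch = [pos_pool[i] for i in rng.integers(len(pos_pool), size=n_pos_batch)]
        if neg_pool:
            batch += [
                neg_pool[i]
                for i in rng.integers(len(neg_pool), size=batch_size - n_pos_batch)
            ]
        imgs = np.stack([b["image"] for b in batch])
        masks = np.stack([b["mask"] for b in batch]).astype(np.float32)
        loss = _forward_loss(model, imgs, masks, cfg)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"segmentation training diverged at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step(lr=cosine_warm_restarts(step, lr, cycle_len=n_steps, warmup=25))
        rec = {"step": step, "loss": float(loss.data), "val_dice": np.nan}
        if (step + 1) % eval_every == 0 or step == n_steps - 1:
            d = validation_dice(model, val_patches)
            rec["val_dice"] = d
            if d >= best_dice:
                best_dice, best_state = d, model.state_dict()
        history.append(rec)
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def predict_patch(model: ResUNet3d, image: np.ndarray) -> np.ndarray:
    """Probability map for one patch (no gradient tape)."""
    from scipy.special import expit

    with no_grad():
        logits, _ = model(Tensor(image[None, ..., None]))
    return expit(logits.data[0, ..., 0])


def validation_dice(model: ResUNet3d, val_patches: list[dict], thr: float = 0.5) -> float:
    """Mean binary Dice over validation patches at threshold ``thr``."""
    dices = []
    for p in val_patches:
        pm = predict_patch(model, p["image"]) >= thr
        g = p["mask"] > 0.5
        if not pm.any() and not g.any():
            dices.append(1.0)
        else:
            dices.append(2.0 * (pm & g).sum() / max(pm.sum() + g.sum(), 1))
    return float(np.mean(dices))


def predict_volume(
    model: ResUNet3d, vol: Volume, cfg: SegConfig, tile: int | None = None
) -> SegPrediction:
    """Sliding-window probability map over a full scan (tiles of
    ``tile`` or ``cfg.patch_size`` voxels with 8-voxel overlap,
    max-combined).  ``tile`` must be divisible by ``2**cfg.depth``."""
    size = tile or cfg.patch_size
    if size % (2**cfg.depth) != 0:
        size += 2**cfg.depth - size % (2**cfg.depth)
    stride = max(size - 8, 1)
    shape = np.array(vol.shape)
    prob = np.zeros(vol.shape, dtype=np.float32)
    starts = [
        np.unique(np.clip(np.arange(0, shape[a], stride), 0, max(shape[a] - size, 0)))
        for a in range(3)
    ]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (
                    slice(sx, min(sx + size, shape[0])),
                    slice(sy, min(sy + size, shape[1])),
                    slice(sz, min(sz + size, shape[2])),
                )
                tile = vol.data[sl]
                pad = [(0, size - s.stop + s.start) for s in sl]
                if any(p[1] for p in pad):
                    tile = np.pad(tile, pad)
                p = predict_patch(model, tile.astype(np.float32))
                p = p[: sl[0].stop - sl[0].start, : sl[1].stop - sl[1].start,
                      : sl[2].stop - sl[2].start]
                prob[sl] = np.maximum(prob[sl], p)
    return SegPrediction(prob_map=vol.copy_with(prob))
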