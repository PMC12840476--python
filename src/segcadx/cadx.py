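"""Stage-2 malignancy classification.

A dual-stream classifier (dense 3D convolutional encoder + hierarchical
windowed self-attention encoder) consumes a fixed 32^3 nodule patch at
1 mm; its deep embedding is late-fused with a handcrafted radiomics
vector, f = [z || r], and mapped to a malignancy probability plus
auxiliary attribute estimates (spiculation, lobulation, subtlety).
Monte Carlo dropout supplies epistemic uncertainty.  Label harmonisation
follows the consensus-averaging convention: mean reader score < 3 is
benign, > 3 malignant, exactly 3 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from skimage import measure

from .nn import AdamW, HybridClassifier, Tensor, cosine_warm_restarts, no_grad

RADIOMICS_FEATURES = [
    "mean", "sd", "min", "max", "p25", "p75",
    "volume_mm3", "surface_mm2", "sphericity", "compactness", "surface_to_volume",
]


@dataclass
class NodulePatch:
    cube: np.ndarray  # fixed-size crop, intensities in [0, 1]
    mask: np.ndarray  # matching binary nodule mask
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float32)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.cube.shape != self.mask.shape:
            raise ValueError("cube and mask shapes differ")


@dataclass
class MalignancyPrediction:
    prob: float
    attributes: dict
    uncertainty_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0 or self.uncertainty_sd < 0:
            raise ValueError("invalid prediction")


# ----------------------------------------------------------------------
# label harmonisation
# ----------------------------------------------------------------------

def binarize_malignancy(reader_scores) -> str:
    """Consensus averaging of 1-5 reader scores: mean < 3 -> 'benign',
    > 3 -> 'malignant', exactly 3 -> 'excluded'."""
    scores = np.asarray(reader_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one reader score")
    if np.any((scores < 1) | (scores > 5)):
        raise ValueError("reader scores must lie in [1, 5]")
    m = scores.mean()
    if m < 3:
        return "benign"
    if m > 3:
        return "malignant"
    return "excluded"


# ----------------------------------------------------------------------
# radiomics
# ----------------------------------------------------------------------

def extract_radiomics(patch: NodulePatch) -> np.ndarray:
    """Handcrafted descriptor vector (order: ``RADIOMICS_FEATURES``).

    Intensity statistics are computed over in-mask voxels only; volume is
    voxel count x voxel volume; surface area comes from a marching-cubes
    mesh of the mask; sphericity = pi^(1/3) (6V)^(2/3) / A; compactness =
    36 pi V^2 / A^3 (1 for an ideal sphere); surface_to_volume = A / V.
    """
    if not patch.mask.any():
        raise ValueError("empty nodule mask")
    vals = patch.cube[patch.mask].astype(np.float64)
    voxvol = float(np.prod(patch.spacing_mm))
    volume = patch.mask.sum() * voxvol
    padded = np.pad(patch.mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(patch.spacing_mm)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area
    compactness = 36.0 * np.pi * volume**2 / area**3
    return np.array(
        [
            vals.mean(), vals.std(), vals.min(), vals.max(),
            np.percentile(vals, 25), np.percentile(vals, 75),
            volume, area, sphericity, compactness, area / volume,
        ],
        dtype=np.float32,
    )


def normalize_radiomics(r: np.ndarray) -> np.ndarray:
    """Scale radiomics to comparable magnitudes for network input."""
    r = np.asarray(r, dtype=np.float32).copy()
    if r.ndim == 1:
        r = r[None]
    r[:, 6] = np.log1p(r[:, 6]) / 8.0   # volume_mm3
    r[:, 7] = np.log1p(r[:, 7]) / 8.0   # surface_mm2
    r[:, 10] = np.clip(r[:, 10] / 3.0, 0, 2)  # surface_to_volume
    return r


# ----------------------------------------------------------------------
# model and loss
# ----------------------------------------------------------------------

@dataclass
class CadxConfig:
    use_dense: bool = True
    use_attn: bool = True
    use_radiomics: bool = True
    dropout: float = 0.3
    attr_weights: tuple[float, float, float] = (0.1, 0.1, 0.05)  # beta_j
    patch_size: int = 32

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.attr_weights):
            raise ValueError("attribute weights must be non-negative")


def build_hybrid_classifier(cfg: CadxConfig, seed: int = 0) -> HybridClassifier:
    return HybridClassifier(
        n_radiomics=len(RADIOMICS_FEATURES),
        use_dense=cfg.use_dense,
        use_attn=cfg.use_attn,
        use_radiomics=cfg.use_radiomics,
        dropout=cfg.dropout,
        rng=np.random.default_rng(seed),
    )


def attr_to_unit(score: np.ndarray) -> np.ndarray:
    """Rescale attribute scores from [1, 5] to [0, 1]."""
    return (np.asarray(score, dtype=np.float32) - 1.0) / 4.0


def cadx_loss(
    prob: float,
    label: int,
    attr_pred: np.ndarray,
    attr_target: np.ndarray,
    beta=(0.1, 0.1, 0.05),
) -> float:
    """L = BCE(prob, label) + sum_j beta_j * smooth_l1(attr_j error).

    Attribute inputs are expected on the [0, 1] scale.
    """
    from .cade import smooth_l1

    p = min(max(float(prob), 1e-12), 1 - 1e-12)
    l_bin = -(label * np.log(p) + (1 - label) * np.log(1 - p))
    diffs = np.asarray(attr_pred, dtype=float) - np.asarray(attr_target, dtype=float)
    return float(l_bin + np.sum(np.asarray(beta) * smooth_l1(diffs)))


def _batch_loss(model, cubes, rads, labels, attrs, beta) -> Tensor:
    logit, attr_pred = model(Tensor(cubes[..., None]), Tensor(rads))
    p = logit.sigmoid() * (1.0 - 2e-6) + 1e-6
    y = Tensor(labels.astype(np.float32))
    bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    diff = attr_pred - Tensor(attrs.astype(np.float32))
    absd = (diff * diff + 1e-12).pow(0.5)
    small = (absd.data < 1.0).astype(np.float32)
    sl1 = (diff * diff * 0.5) * Tensor(small) + (absd - 0.5) * Tensor(1.0 - small)
    return bce + (sl1 * Tensor(np.asarray(beta, dtype=np.float32))).mean(axis=0).sum()


def _augment_cube(cube: np.ndarray, rng) -> np.ndarray:
    """Random axis permutation + flips (cube is isotropic, so all 48
    orientations are label-preserving)."""
    cube = np.transpose(cube, rng.permutation(3))
    for ax in range(3):
        if rng.random() < 0.5:
            cube = np.flip(cube, axis=ax)
    return np.ascontiguousarray(cube)


def train_classifier(
    examples: list[dict],
    cfg: CadxConfig,
    seed: int = 0,
    n_steps: int = 300,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> HybridClassifier:
    """Train the hybrid classifier.

    ``examples``: dicts with ``cube`` (S^3 in [0,1]), ``radiomics`` (raw
    vector), ``label`` (0/1), ``attributes`` (3 scores in [1,5]).
    """
    if len({e["label"] for e in examples}) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    model = build_hybrid_classifier(cfg, seed=seed)
    model.drop.rng = np.random.default_rng(seed + 1)
    model.drop_deep.rng = np.random.default_rng(seed + 2)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-4)
    rad_all = normalize_radiomics(np.stack([e["radiomics"] for e in examples]))
    # z-score radiomics on the training set so neither stream dominates
    mu, sd = rad_all.mean(axis=0), rad_all.std(axis=0) + 1e-6
    rad_all = (rad_all - mu) / sd
    model.rad_stats = (mu, sd)
    for step in range(n_steps):
        idx = rng.integers(len(examples), size=batch_size)
        # geometric augmentation: random axis permutations and flips
        # (radiomics are invariant to these, so the vector is reused)
        cubes = np.stack(
            [_augment_cube(examples[i]["cube"], rng) for i in idx]
        ).astype(np.float32)
        labels = np.array([examples[i]["label"] for i in idx])
        attrs = attr_to_unit(np.stack([examples[i]["attributes"] for i in idx]))
        loss = _batch_loss(model, cubes, rad_all[idx], labels, attrs, cfg.attr_weights)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"classifier training diverged at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step(lr=cosine_warm_restarts(step, lr, cycle_len=n_steps, warmup=25))
    return model


def predict_logit(model: HybridClassifier, cubes: np.ndarray, radiomics: np.ndarray,
                  stochastic: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Malignancy logits and attribute estimates for a batch."""
    model.set_stochastic(stochastic)
    rad = normalize_radiomics(np.asarray(radiomics, dtype=np.float32))
    stats = getattr(model, "rad_stats", None)
    if stats is not None:
        rad = (rad - stats[0]) / stats[1]
    with no_grad():
        logit, attrs = model(
            Tensor(np.asarray(cubes, dtype=np.float32)[..., None]),
            Tensor(rad),
        )
    return logit.data, attrs.data


def predict_with_uncertainty(
    model: HybridClassifier,
    cube: np.ndarray,
    radiomics: np.ndarray,
    n_mc: int = 20,
    seed: int = 0,
) -> MalignancyPrediction:
    """Monte Carlo dropout: mean and sd of ``n_mc`` stochastic passes."""
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2 for an uncertainty estimate")
    model.drop.rng = np.random.default_rng(seed)
    if hasattr(model, "drop_deep"):
        model.drop_deep.rng = np.random.default_rng(seed + 10)
    probs, attr_draws = [], []
    for _ in range(n_mc):
        logit, attrs = predict_logit(
            model, cube[None], radiomics[None], stochastic=True
        )
        probs.append(expit(logit[0]))
        attr_draws.append(attrs[0])
    model.set_stochastic(False)
    probs = np.array(probs)
    mean_attr = np.mean(attr_draws, axis=0) * 4.0 + 1.0  # back to [1, 5]
    return MalignancyPrediction(
        prob=float(probs.mean()),
        attributes={
            "spiculation": float(mean_attr[0]),
            "lobulation": float(mean_attr[1]),
            "subtlety": float(mean_attr[2]),
        },
        uncertainty_sd=float(probs.std(ddof=0)),
    )


# ----------------------------------------------------------------------
# scan-level aggregation
# ----------------------------------------------------------------------

def aggregate_scan_risk(
    probs, method: str = "topK", K: int = 3, attention_scale: float = 4.0
) -> float:
    """Aggregate per-candidate malignancy probabilities to scan risk.

    ``topK``: mean of the K highest probabilities (all if fewer).
    ``attention``: softmax-weighted mean, scores = attention_scale * p,
    so high-risk candidates dominate.  No candidates -> 0.
    """
    p = np.sort(np.asarray(probs, dtype=float))[::-1]
    if p.size == 0:
        return 0.0
    if method == "topK":
        return float(p[: max(K, 1)].mean())
    if method == "attention":
        w = np.exp(attention_scale * p - (attention_scale * p).max())
        w /= w.sum()
        return float((w * p).sum())
    raise ValueError(f"unknown aggregation method {method!r}")
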