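"""Stage-1 candidate detection.

Candidates are extracted from the segmentation probability map as
26-neighbourhood local maxima, pruned by greedy distance-based NMS, and
rescored by a lightweight 2.5D refinement head that ingests a stack of
adjacent axial slices and predicts nodule-vs-non-nodule logits plus
regression targets (radius in mm, sub-voxel centre offsets in voxels).
Detections are matched to ground truth with the centre-within-radius hit
criterion; duplicate detections of an already-hit nodule are ignored
rather than counted as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import AdamW, RefineHead2p5D, Tensor, cosine_warm_restarts, no_grad
from .seg import equivalent_diameter_mm
from .volume import Volume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Candidate:
    center_mm: np.ndarray
    radius_mm: float
    score: float
    series_id: str = ""

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.radius_mm < 0:
            raise ValueError("radius must be non-negative")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class DetectionLossWeights:
    w_cls: float = 1.0  # classification weight in the head-only loss
    w_loc: float = 1.0  # localization weight in the head-only loss
    phi1: float = 1.0  # classification weight in the joint Stage-1 loss
    phi2: float = 0.5  # regression weight in the joint Stage-1 loss

    def __post_init__(self) -> None:
        if min(self.w_cls, self.w_loc, self.phi1, self.phi2) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_labels: list[str] = field(default_factory=list)  # 'TP' | 'FP' | 'IGN'
    nodule_hit: list[bool] = field(default_factory=list)


# ----------------------------------------------------------------------
# candidate extraction
# ----------------------------------------------------------------------

def extract_candidates(
    prob: Volume,
    min_score: float = 0.35,
    nms_dist_mm: float = 5.0,
    series_id: str = "",
    component_thr: float = 0.35,
) -> list[Candidate]:
    """Local maxima of the probability map, converted to world mm and
    pruned by NMS.  Candidate radii are initialised from the equivalent
    diameter of the thresholded component containing each peak."""
    P = prob.data
    peaks = (P == ndimage.maximum_filter(P, size=3)) & (P >= min_score)
    if not peaks.any():
        return []
    labels, _ = ndimage.label(P >= component_thr, structure=_CONN26)
    counts = np.bincount(labels.ravel())
    cands = []
    for idx in np.argwhere(peaks):
        lab = labels[tuple(idx)]
        radius = (
            equivalent_diameter_mm(counts[lab], prob.spacing_mm) / 2.0
            if lab > 0
            else 1.5
        )
        cands.append(
            Candidate(
                center_mm=prob.voxel_to_world(idx),
                radius_mm=float(radius),
                score=float(P[tuple(idx)]),
                series_id=series_id,
            )
        )
    return nms(cands, nms_dist_mm)


def nms(cands: list[Candidate], dist_mm: float) -> list[Candidate]:
    """Greedy distance-based non-maximum suppression.

    Candidates are visited in descending score (ties keep input order);
    one is kept iff its centre is >= ``dist_mm`` from every kept centre.
    """
    order = sorted(range(len(cands)), key=lambda i: (-cands[i].score, i))
    kept: list[Candidate] = []
    for i in order:
        c = cands[i]
        if all(np.linalg.norm(c.center_mm - k.center_mm) >= dist_mm for k in kept):
            kept.append(c)
    return kept


def build_slab(v: Volume, c: Candidate, k_slices: int = 5, size_mm: float = 32.0) -> np.ndarray:
    """2.5D stack: ``k_slices`` adjacent axial slices centred on the
    candidate, each ``size_mm`` square, stacked on the last axis.
    Out-of-volume regions are zero-padded.  Returns (S, S, k)."""
    idx = np.round(v.world_to_voxel(c.center_mm)).astype(int)
    s = int(round(size_mm / v.spacing_mm[0]))
    half_k = k_slices // 2
    slab = np.zeros((s, s, k_slices), dtype=np.float32)
    for j, dz in enumerate(range(-half_k, half_k + 1)):
        z = idx[2] + dz
        if not 0 <= z < v.shape[2]:
            continue
        lo = idx[:2] - s // 2
        hi = lo + s
        src = tuple(slice(max(l, 0), min(h, n)) for l, h, n in zip(lo, hi, v.shape[:2]))
        dst = tuple(
            slice(max(-l, 0), max(-l, 0) + (sl.stop - sl.start))
            for l, sl in zip(lo, src)
        )
        slab[dst[0], dst[1], j] = v.data[src[0], src[1], z]
    return slab


# ----------------------------------------------------------------------
# detection losses
# ----------------------------------------------------------------------

def smooth_l1(x: float | np.ndarray) -> np.ndarray:
    """Smooth-l1: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    x = np.abs(np.asarray(x, dtype=float))
    return np.where(x < 1.0, 0.5 * x**2, x - 0.5)


def detection_losses(
    pred_probs: np.ndarray,
    pred_reg: np.ndarray,
    target_class: int,
    target_reg: np.ndarray,
    w: DetectionLossWeights | None = None,
    seg_loss_value: float = 0.0,
) -> dict:
    """Per-candidate detection losses.

    ``pred_probs`` is a probability simplex over {non-nodule, nodule};
    regression targets are (radius_mm, 3 sub-voxel offsets), averaged in
    the smooth-l1 term.  ``L_det`` is the head-only loss; ``L_cade`` adds
    the current segmentation loss to the phi-weighted head terms.
    """
    w = w or DetectionLossWeights()
    p = np.asarray(pred_probs, dtype=float)
    if p.ndim != 1 or not np.isclose(p.sum(), 1.0, atol=1e-5):
        raise ValueError("pred_probs must be a probability simplex")
    l_cls = float(-np.log(max(p[target_class], 1e-12)))
    l_loc = float(np.mean(smooth_l1(np.asarray(pred_reg) - np.asarray(target_reg))))
    return {
        "L_cls": l_cls,
        "L_loc": l_loc,
        "L_det": w.w_cls * l_cls + w.w_loc * l_loc,
        "L_cade": seg_loss_value + w.phi1 * l_cls + w.phi2 * l_loc,
    }


# ----------------------------------------------------------------------
# refinement head training / application
# ----------------------------------------------------------------------

def train_refine_head(
    examples: list[dict],
    seed: int = 0,
    n_steps: int = 200,
    batch_size: int = 16,
    lr: float = 3e-3,
    k_slices: int = 5,
    weights: DetectionLossWeights | None = None,
) -> RefineHead2p5D:
    """Train the 2.5D head on labelled slabs.

    ``examples``: dicts with ``slab`` (S, S, k), ``label`` (0/1) and, for
    positives, ``reg`` = (radius_mm, off_x, off_y, off_z).
    """
    w = weights or DetectionLossWeights()
    rng = np.random.default_rng(seed)
    model = RefineHead2p5D(k_slices=k_slices, rng=np.random.default_rng(seed))
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-5)
    for step in range(n_steps):
        batch = [examples[i] for i in rng.integers(len(examples), size=batch_size)]
        slabs = np.stack([b["slab"] for b in batch])[:, None]  # (B,1,S,S,k)
        ys = np.array([b["label"] for b in batch], dtype=int)
        cls_logits, reg = model(Tensor(slabs))
        logp = (cls_logits.softmax(axis=-1) * (1.0 - 2e-6) + 1e-6).log()
        onehot = np.eye(2, dtype=np.float32)[ys]
        loss = -(logp * Tensor(onehot)).sum(axis=-1).mean() * w.w_cls
        pos = ys == 1
        if pos.any():
            tgt = np.zeros((len(batch), 4), dtype=np.float32)
            for i, b in enumerate(batch):
                if b["label"] == 1:
                    tgt[i] = b.get("reg", np.zeros(4))
            diff = reg - Tensor(tgt)
            # smooth-l1 via |x| branches composed from autograd primitives
            absd = (diff * diff + 1e-12).pow(0.5)
            mask_small = (absd.data < 1.0).astype(np.float32)
            sl1 = (diff * diff * 0.5) * Tensor(mask_small) + (absd - 0.5) * Tensor(
                1.0 - mask_small
            )
            posmask = pos.astype(np.float32)[:, None]
            loss = loss + w.w_loc * (sl1 * Tensor(posmask)).sum() * (
                1.0 / max(pos.sum() * 4, 1)
            )
        if not np.isfinite(loss.data):
            raise RuntimeError(f"refinement head diverged at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step(lr=cosine_warm_restarts(step, lr, cycle_len=n_steps, warmup=25))
    return model


def score_slabs(model: RefineHead2p5D, slabs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodule probabilities and regression outputs for a slab batch."""
    with no_grad():
        cls_logits, reg = model(Tensor(np.asarray(slabs, dtype=np.float32)[:, None]))
    e = np.exp(cls_logits.data - cls_logits.data.max(axis=-1, keepdims=True))
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs[:, 1], reg.data


def refine_candidates(
    model: RefineHead2p5D,
    cands: list[Candidate],
    vol: Volume,
    threshold: float = 0.1,
    k_slices: int = 5,
    size_mm: float = 32.0,
    apply_offsets: bool = True,
) -> list[Candidate]:
    """Rescore candidates with the 2.5D head; apply predicted offsets and
    radii; drop candidates below the confidence threshold."""
    if not cands:
        return []
    slabs = np.stack([build_slab(vol, c, k_slices, size_mm) for c in cands])
    probs, reg = score_slabs(model, slabs)
    out = []
    for c, p, r in zip(cands, probs, reg):
        if p < threshold:
            continue
        center = c.center_mm.copy()
        if apply_offsets:
            center = center + r[1:4] * vol.spacing_mm
        out.append(
            Candidate(
                center_mm=center,
                radius_mm=float(max(r[0], 0.0)) if apply_offsets else c.radius_mm,
                score=float(p),
                series_id=c.series_id,
            )
        )
    return out


def hard_negative_mining(
    fp_examples: list[dict], pool: list[dict], n_mined: int = 20
) -> list[dict]:
    """Augment a training pool with the highest-scored false positives.

    ``fp_examples``: dicts with ``slab`` and ``score``; the top ``n_mined``
    are appended once each as negatives (label 0)."""
    ranked = sorted(fp_examples, key=lambda e: -e.get("score", 0.0))[:n_mined]
    seen = {id(e.get("slab")) for e in pool}
    out = list(pool)
    for e in ranked:
        if id(e["slab"]) in seen:
            continue
        out.append({"slab": e["slab"], "label": 0})
    return out


# ----------------------------------------------------------------------
# detection / ground-truth matching
# ----------------------------------------------------------------------

def match_detections(
    dets: list[Candidate], nodules: list[tuple[np.ndarray, float]]
) -> MatchResult:
    """Match detections to ground-truth nodules (centre, radius_mm).

    A detection is a true positive iff its centre lies within (<=) the
    annotated nodule radius; the highest-scoring detection claims each
    nodule; further detections inside an already-hit nodule are ignored;
    everything else is a false positive.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    hit = [False] * len(nodules)
    labels = [""] * len(dets)
    for i in order:
        d = dets[i]
        dists = [np.linalg.norm(d.center_mm - np.asarray(c)) for c, _ in nodules]
        inside = [j for j, (dist, (_, r)) in enumerate(zip(dists, nodules)) if dist <= r]
        unhit = [j for j in inside if not hit[j]]
        if unhit:
            j = min(unhit, key=lambda j: dists[j])
            hit[j] = True
            labels[i] = "TP"
        elif inside:
            labels[i] = "IGN"
        else:
            labels[i] = "FP"
    tp = labels.count("TP")
    fp = labels.count("FP")
    return MatchResult(
        tp=tp, fp=fp, fn=len(nodules) - tp, det_labels=labels, nodule_hit=hit
    )


# ----------------------------------------------------------------------
# CSV dialect
# ----------------------------------------------------------------------

DETECTION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "radius_mm", "probability"]


def detections_frame(dets: list[Candidate]) -> pd.DataFrame:
    rows = [
        {
            "seriesuid": d.series_id,
            "coordX": d.center_mm[0],
            "coordY": d.center_mm[1],
            "coordZ": d.center_mm[2],
            "radius_mm": d.radius_mm,
            "probability": d.score,
        }
        for d in dets
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detections_from_frame(df: pd.DataFrame) -> list[Candidate]:
    return [
        Candidate(
            center_mm=np.array([r.coordX, r.coordY, r.coordZ]),
            radius_mm=float(getattr(r, "radius_mm", 0.0)),
            score=float(r.probability),
            series_id=str(r.seriesuid),
        )
        for r in df.itertuples()
    ]
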