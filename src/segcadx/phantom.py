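"""Synthetic low-dose chest-CT phantoms with ground truth.

Generates 3D volumes that carry the statistical structure the detection /
diagnosis pipeline assumes: two ellipsoidal lung fields (~ -850 HU) inside
a soft-tissue body with rib-like high-density arcs, random-walk vessel
tubes inside the lungs, and nodules of controlled diameter and attenuation
class (solid, part-solid, ground-glass).  Malignancy is generated from the
shape attributes (a logistic link on spiculation + lobulation), so a
classifier can genuinely learn it from the rendered morphology; simulated
per-reader malignancy scores (4 readers, 1-5) are consistent with the
label under consensus averaging.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import Volume

ATTENUATION_CLASSES = ("solid", "part_solid", "ground_glass")

# HU levels of the rendered tissue classes
HU_AIR = -1000.0
HU_LUNG = -850.0
HU_BODY = 40.0
HU_RIB = 700.0
HU_VESSEL = 50.0


class GenerationError(RuntimeError):
    """Nodule placement failed after bounded retries."""


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_scans: int = 10
    nodules_per_scan: tuple[int, int] = (1, 3)  # inclusive range
    diameter_mm: tuple[float, float] = (3.0, 16.0)
    stratum_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # <=6, 6-10, >10
    attenuation_mix: dict = field(
        default_factory=lambda: {"solid": 0.6, "part_solid": 0.25, "ground_glass": 0.15}
    )
    malignant_fraction: float = 0.5
    vessel_density: int = 5  # tubes per lung
    noise_sd_hu: float = 20.0
    seed: int = 0
    # logistic link p(malignant | attributes); None => deterministic sign link
    # (malignant iff the spiculation/lobulation contrast is positive).
    attribute_link_scale: float | None = 3.0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.attenuation_mix.values()), 1.0):
            raise ValueError("attenuation_mix must sum to 1")
        if not np.isclose(sum(self.stratum_mix), 1.0):
            raise ValueError("stratum_mix must sum to 1")
        if self.diameter_mm[0] < 3.0 or self.diameter_mm[1] <= self.diameter_mm[0]:
            raise ValueError("diameter range must be increasing and start >= 3 mm")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in [0, 1]")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        if np.any(extent < 48.0):
            raise ValueError("grid too small to contain the lung ellipsoids")


@dataclass
class NoduleSpec:
    center_mm: np.ndarray
    diameter_mm: float
    attenuation: str
    malignant: bool
    attribute_scores: dict  # spiculation / lobulation / subtlety in [1, 5]
    reader_scores: list[int]  # 4 simulated per-reader malignancy scores 1-5
    nodule_id: int = 0


@dataclass
class PhantomScan:
    volume: Volume
    lung_mask_gt: Volume
    nodule_mask_gt: Volume  # labelled: nodule i has label i+1
    nodules: list[NoduleSpec]
    series_id: str


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _paint_sphere(data: np.ndarray, spacing, center_vox, radius_mm, value) -> None:
    r_vox = np.ceil(radius_mm / np.asarray(spacing)).astype(int)
    lo = np.maximum(np.round(center_vox).astype(int) - r_vox - 1, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + r_vox + 2, data.shape)
    if np.any(lo >= hi):
        return
    sub = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
    )
    c_mm = np.asarray(center_vox) * np.asarray(spacing)
    d2 = sum((g - c) ** 2 for g, c in zip(sub, c_mm))
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    data[region][d2 <= radius_mm**2] = value


def _nodule_shape(rng, radius_mm, spacing, n_spikes, n_lobes) -> np.ndarray:
    """Rasterize a nodule: sphere core plus thin radial spikes (spiculation)
    and offset lobes (lobulation).  Returns a local binary mask."""
    reach = 1.7 * radius_mm
    half = int(np.ceil(reach / min(spacing))) + 2
    n = 2 * half + 1
    ax = [(np.arange(n) - half) * s for s in spacing]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    dist = np.linalg.norm(pts, axis=-1)

    spike_dirs = rng.normal(size=(max(n_spikes, 0), 3))
    lobe_dirs = rng.normal(size=(max(n_lobes, 0), 3))

    def build(core_r: float) -> np.ndarray:
        mask = dist <= core_r
        spike_w = max(0.7, 0.1 * core_r)
        for d in spike_dirs:
            u = d / np.linalg.norm(d)
            proj = pts @ u
            perp = np.sqrt(np.maximum(dist**2 - proj**2, 0.0))
            mask |= (proj > 0) & (proj <= 1.6 * core_r) & (perp <= spike_w)
        for d in lobe_dirs:
            u = d / np.linalg.norm(d)
            c = u * core_r
            mask |= np.linalg.norm(pts - c, axis=-1) <= 0.45 * core_r
        return mask

    # one corrective pass so the equivalent-sphere diameter matches the
    # nominal diameter despite the extra spike/lobe volume
    voxvol = float(np.prod(spacing))
    mask = build(radius_mm)
    d_eq = 2.0 * (3.0 * mask.sum() * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)
    mask = build(radius_mm * (2.0 * radius_mm / d_eq))
    return mask


# ----------------------------------------------------------------------
# attribute / label model
# ----------------------------------------------------------------------

def _sample_nodule_labels(rng, cfg: PhantomConfig):
    """Draw (attributes, malignant, reader_scores) for one nodule.

    A latent aggressiveness bit (rate ``malignant_fraction``) selects the
    attribute regime; the final label is then drawn from a logistic link on
    the spiculation/lobulation contrast, so the label is a learnable but
    noisy function of rendered shape.
    """
    aggressive = rng.random() < cfg.malignant_fraction
    if aggressive:
        spic = np.clip(rng.normal(4.0, 0.6), 1, 5)
        lob = np.clip(rng.normal(3.8, 0.6), 1, 5)
    else:
        spic = np.clip(rng.normal(1.8, 0.6), 1, 5)
        lob = np.clip(rng.normal(2.0, 0.6), 1, 5)
    subtlety = float(np.clip(rng.normal(3.0, 0.8), 1, 5))
    u = 0.6 * (spic - 3.0) + 0.4 * (lob - 3.0)
    if cfg.attribute_link_scale is None:
        malignant = u > 0
    else:
        malignant = rng.random() < 1.0 / (1.0 + np.exp(-cfg.attribute_link_scale * u))

    true_score = rng.uniform(3.6, 4.8) if malignant else rng.uniform(1.2, 2.6)
    for _ in range(20):
        scores = np.clip(
            np.round(true_score + rng.integers(-1, 2, size=4)), 1, 5
        ).astype(int)
        mean = scores.mean()
        if (malignant and mean > 3) or (not malignant and mean < 3):
            break
    else:
        scores = np.full(4, int(np.clip(round(true_score), 1, 5)))
    attrs = {"spiculation": float(spic), "lobulation": float(lob), "subtlety": subtlety}
    return attrs, bool(malignant), [int(s) for s in scores]


def _sample_diameter(rng, cfg: PhantomConfig) -> float:
    lo, hi = cfg.diameter_mm
    stratum = rng.choice(3, p=cfg.stratum_mix)
    bounds = [(lo, min(6.0, hi)), (max(6.0, lo), min(10.0, hi)), (max(10.0, lo), hi)]
    a, b = bounds[stratum]
    if b <= a:  # configured range does not reach this stratum; fall back
        return float(rng.uniform(lo, hi))
    return float(rng.uniform(a, b))


# ----------------------------------------------------------------------
# scan generation
# ----------------------------------------------------------------------

def _generate_scan(cfg: PhantomConfig, rng, series_id: str) -> PhantomScan:
    shape = tuple(cfg.grid_shape)
    spacing = np.asarray(cfg.spacing_mm, dtype=float)
    extent = np.array(shape) * spacing
    origin = rng.uniform(-200.0, 0.0, size=3)  # arbitrary world origin

    data = np.full(shape, HU_AIR, dtype=np.float32)
    body = _ellipsoid_mask(shape, spacing, extent / 2, extent * 0.47)
    data[body] = HU_BODY

    # rib-like arcs: high-density shell bands of the body ellipsoid
    shell = body & ~_ellipsoid_mask(shape, spacing, extent / 2, extent * 0.44)
    zmm = np.arange(shape[2]) * spacing[2]
    bands = (np.floor(zmm / 8.0) % 2 == 0)[None, None, :]
    data[shell & np.broadcast_to(bands, shape)] = HU_RIB

    # two lung ellipsoids
    lungs = np.zeros(shape, dtype=bool)
    for side in (-1, +1):
        c = extent / 2 + np.array([side * extent[0] * 0.22, 0.0, 0.0])
        radii = extent * np.array([0.17, 0.30, 0.38])
        lungs |= _ellipsoid_mask(shape, spacing, c, radii)
    lungs &= body
    data[lungs] = HU_LUNG

    # vessels: random-walk tubes inside the lungs
    lung_idx = np.argwhere(lungs)
    for _ in range(2 * cfg.vessel_density):
        pos = lung_idx[rng.integers(len(lung_idx))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(1.0, 2.0)
        for _ in range(30):
            if lungs[tuple(np.clip(np.round(pos).astype(int), 0, np.array(shape) - 1))]:
                _paint_sphere(data, spacing, pos, radius, HU_VESSEL)
            direction += 0.4 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos += direction * (1.5 / spacing)

    # nodules
    nodule_mask = np.zeros(shape, dtype=np.int16)
    nodules: list[NoduleSpec] = []
    n_nodules = int(rng.integers(cfg.nodules_per_scan[0], cfg.nodules_per_scan[1] + 1))
    for nid in range(n_nodules):
        diameter = _sample_diameter(rng, cfg)
        attrs, malignant, scores = _sample_nodule_labels(rng, cfg)
        atten = rng.choice(
            list(cfg.attenuation_mix.keys()), p=list(cfg.attenuation_mix.values())
        )
        n_spikes = max(0, int(round((attrs["spiculation"] - 2.5) * 2)))
        n_lobes = max(0, int(round((attrs["lobulation"] - 2.5) * 1.5)))
        local = _nodule_shape(rng, diameter / 2, spacing, n_spikes, n_lobes)
        half = (np.array(local.shape) - 1) // 2

        placed = False
        for _ in range(200):
            cand = lung_idx[rng.integers(len(lung_idx))]
            lo = cand - half
            hi = lo + np.array(local.shape)
            if np.any(lo < 0) or np.any(hi > np.array(shape)):
                continue
            region = tuple(slice(l, h) for l, h in zip(lo, hi))
            if not lungs[region][local].all():
                continue  # shape must lie fully inside the lung field
            if (nodule_mask[region][local] != 0).any():
                continue
            too_close = any(
                np.linalg.norm((cand * spacing) - ((n.center_mm - origin)))
                < (diameter + n.diameter_mm) / 2 + 5.0
                for n in nodules
            )
            if too_close:
                continue
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place nodule {nid} (d={diameter:.1f} mm) in {series_id}"
            )

        # intensities by attenuation class
        if atten == "solid":
            hu = rng.uniform(-50.0, 100.0)
            data[region][local] = hu
        elif atten == "ground_glass":
            hu = rng.uniform(-700.0, -500.0)
            data[region][local] = hu
        else:  # part-solid: ground-glass halo with a solid core
            data[region][local] = rng.uniform(-700.0, -500.0)
            dist = np.linalg.norm(
                (np.stack(np.meshgrid(*[np.arange(n) for n in local.shape],
                                      indexing="ij"), axis=-1)
                 - half) * spacing, axis=-1)
            core = local & (dist <= 0.55 * diameter / 2)
            data[region][core] = rng.uniform(0.0, 80.0)
        nodule_mask[region][local] = nid + 1

        nodules.append(
            NoduleSpec(
                center_mm=origin + cand * spacing,
                diameter_mm=float(diameter),
                attenuation=str(atten),
                malignant=malignant,
                attribute_scores=attrs,
                reader_scores=scores,
                nodule_id=nid,
            )
        )

    data += rng.normal(0.0, cfg.noise_sd_hu, size=shape).astype(np.float32)
    vol = Volume(data, spacing, origin)
    return PhantomScan(
        volume=vol,
        lung_mask_gt=Volume(lungs, spacing, origin),
        nodule_mask_gt=Volume(nodule_mask, spacing, origin),
        nodules=nodules,
        series_id=series_id,
    )


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> list[PhantomScan]:
    """Generate ``config.n_scans`` phantom scans, deterministic given seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    return [
        _generate_scan(config, rng, f"phantom-{seed}-{i:03d}")
        for i in range(config.n_scans)
    ]


# ----------------------------------------------------------------------
# annotation tables and splits
# ----------------------------------------------------------------------

ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]
MALIGNANCY_COLUMNS = [
    "seriesuid", "nodule_id", "score_r1", "score_r2", "score_r3", "score_r4",
    "spiculation", "lobulation", "subtlety",
]


def annotations_frame(scans: list[PhantomScan]) -> pd.DataFrame:
    rows = [
        {
            "seriesuid": s.series_id,
            "coordX": n.center_mm[0],
            "coordY": n.center_mm[1],
            "coordZ": n.center_mm[2],
            "diameter_mm": n.diameter_mm,
        }
        for s in scans
        for n in s.nodules
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def malignancy_frame(scans: list[PhantomScan]) -> pd.DataFrame:
    rows = [
        {
            "seriesuid": s.series_id,
            "nodule_id": n.nodule_id,
            **{f"score_r{i + 1}": n.reader_scores[i] for i in range(4)},
            **n.attribute_scores,
        }
        for s in scans
        for n in s.nodules
    ]
    return pd.DataFrame(rows, columns=MALIGNANCY_COLUMNS)


def write_annotations(scans: list[PhantomScan], out_dir: str) -> tuple[str, str]:
    """Write the annotation and malignancy CSVs; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    ann_path = os.path.join(out_dir, "annotations.csv")
    mal_path = os.path.join(out_dir, "malignancy.csv")
    annotations_frame(scans).to_csv(ann_path, index=False)
    malignancy_frame(scans).to_csv(mal_path, index=False)
    return ann_path, mal_path


def split_patients(scans: list[PhantomScan], k_folds: int, seed: int = 0) -> dict[str, int]:
    """Patient-level k-fold assignment: each series in exactly one fold,
    fold sizes differing by at most one."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > len(scans):
        raise ValueError("k_folds exceeds number of scans")
    ids = [s.series_id for s in scans]
    order = np.random.default_rng(seed).permutation(len(ids))
    return {ids[j]: i % k_folds for i, j in enumerate(order)}
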