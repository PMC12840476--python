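"""End-to-end orchestration: phantom generation -> preprocessing ->
segmentation training -> candidate detection + 2.5D refinement ->
malignancy classification -> temperature calibration -> evaluation.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible.  Train and test phantom cohorts are
generated from disjoint seeds, which enforces patient-level separation by
construction; the run report records both id lists and every fitting step
receives only the training cohort.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import cade, cadx, calibrate, evaluate, phantom, seg
from .preprocess import apply_lung_mask, hu_window_normalize
from .seg import _extract_patch  # shared cubic cropping helper
from .volume import LungMask, Volume


def _preprocessed(scan: phantom.PhantomScan) -> Volume:
    """Windowed, normalized, lung-masked representation of a scan."""
    return apply_lung_mask(
        hu_window_normalize(scan.volume), LungMask(scan.lung_mask_gt)
    )

STAGE_SEED_OFFSETS = {
    "phantom_train": 11, "phantom_test": 211, "seg": 31, "refine": 41,
    "cadx": 51, "eval": 61,
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    n_train: int = 20
    n_test: int = 10
    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    seg: seg.SegConfig = field(
        default_factory=lambda: seg.SegConfig(depth=2, base_channels=8, patch_size=24)
    )
    seg_steps: int = 350
    seg_batch: int = 3
    refine_steps: int = 1200
    refine_scans: int = 10  # train scans mined for refinement-head slabs
    cadx: cadx.CadxConfig = field(default_factory=cadx.CadxConfig)
    cadx_steps: int = 300
    candidate_min_score: float = 0.35
    nms_dist_mm: float = 5.0
    refine_threshold: float = 0.02
    cube_size: int = 32
    top_k: int = 3


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return (cfg.seed * 1000 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _phantoms(cfg: RunConfig, stage: str, n: int) -> list[phantom.PhantomScan]:
    import dataclasses

    pcfg = dataclasses.replace(cfg.phantom, n_scans=n)
    return phantom.generate_phantom(pcfg, seed=_stage_seed(cfg, stage))


def _label_candidates(cands, scan: phantom.PhantomScan):
    """Classification/regression targets for refinement-head training."""
    nodules = [(n.center_mm, n.diameter_mm / 2.0) for n in scan.nodules]
    out = []
    for c in cands:
        dists = [np.linalg.norm(c.center_mm - ctr) for ctr, _ in nodules]
        j = int(np.argmin(dists)) if dists else -1
        if j >= 0 and dists[j] <= nodules[j][1]:
            n = scan.nodules[j]
            off = (n.center_mm - c.center_mm) / scan.volume.spacing_mm
            out.append((1, np.array([n.diameter_mm / 2.0, *off], dtype=np.float32)))
        else:
            out.append((0, None))
    return out


def _nodule_examples(scans, cube_size: int) -> list[dict]:
    """Classifier training/evaluation examples from ground-truth nodules."""
    examples = []
    for s in scans:
        img = _preprocessed(s).data
        for n in s.nodules:
            label = cadx.binarize_malignancy(n.reader_scores)
            if label == "excluded":
                continue
            center = np.round(s.volume.world_to_voxel(n.center_mm)).astype(int)
            cube = _extract_patch(img, center, cube_size).astype(np.float32)
            mask = _extract_patch(
                (s.nodule_mask_gt.data == n.nodule_id + 1).astype(np.float32),
                center, cube_size,
            ) > 0.5
            patch = cadx.NodulePatch(cube=cube, mask=mask,
                                     spacing_mm=s.volume.spacing_mm)
            examples.append(
                {
                    "cube": cube,
                    "radiomics": cadx.extract_radiomics(patch),
                    "label": 1 if label == "malignant" else 0,
                    "attributes": np.array(
                        [n.attribute_scores["spiculation"],
                         n.attribute_scores["lobulation"],
                         n.attribute_scores["subtlety"]]
                    ),
                    "series_id": s.series_id,
                    "nodule_id": n.nodule_id,
                }
            )
    return examples


def _detect_scan(seg_model, head, scan, cfg: RunConfig):
    norm = _preprocessed(scan)
    pred = seg.predict_volume(seg_model, norm, cfg.seg, tile=max(scan.volume.shape))
    # anatomical masking: detections are restricted to the lung fields
    pred.prob_map.data *= scan.lung_mask_gt.data
    cands = cade.extract_candidates(
        pred.prob_map, cfg.candidate_min_score, cfg.nms_dist_mm,
        series_id=scan.series_id,
    )
    if head is not None:
        cands = cade.refine_candidates(
            head, cands, norm, threshold=cfg.refine_threshold
        )
    return pred, cands


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute the full pipeline; write artifacts and a metrics report."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    train = _phantoms(cfg, "phantom_train", cfg.n_train)
    test = _phantoms(cfg, "phantom_test", cfg.n_test)
    report["train_series"] = [s.series_id for s in train]
    report["test_series"] = [s.series_id for s in test]
    assert not set(report["train_series"]) & set(report["test_series"])
    ann_train = phantom.write_annotations(train, os.path.join(cfg.out_dir, "train"))
    ann_test = phantom.write_annotations(test, os.path.join(cfg.out_dir, "test"))
    report["artifacts"] = {"annotations_train": ann_train[0],
                          "malignancy_train": ann_train[1],
                          "annotations_test": ann_test[0],
                          "malignancy_test": ann_test[1]}

    # ---- Stage 0: segmentation -------------------------------------
    seg_seed = _stage_seed(cfg, "seg")
    patches = []
    for i, s in enumerate(train):
        patches.extend(seg.sample_patches(s, cfg.seg, seed=seg_seed + i))
    seg_model, history = seg.train_segmentation(
        patches, cfg.seg, seed=seg_seed, n_steps=cfg.seg_steps,
        batch_size=cfg.seg_batch,
    )
    hist_path = os.path.join(cfg.out_dir, "seg_history.csv")
    history.to_csv(hist_path, index=False)
    report["artifacts"]["seg_history"] = hist_path

    # ---- Stage 1: candidates + refinement head ---------------------
    refine_examples = []
    for s in train[: cfg.refine_scans]:
        norm = _preprocessed(s)
        pred = seg.predict_volume(seg_model, norm, cfg.seg,
                                  tile=max(s.volume.shape))
        pred.prob_map.data *= s.lung_mask_gt.data
        cands = cade.extract_candidates(
            pred.prob_map, cfg.candidate_min_score, cfg.nms_dist_mm,
            series_id=s.series_id,
        )
        for c, (label, reg) in zip(cands, _label_candidates(cands, s)):
            ex = {"slab": cade.build_slab(norm, c), "label": label,
                  "score": c.score}
            if label:
                ex["reg"] = reg
            refine_examples.append(ex)
        for n in s.nodules:  # guaranteed positives at ground-truth centres
            c = cade.Candidate(n.center_mm, n.diameter_mm / 2, 1.0, s.series_id)
            refine_examples.append(
                {"slab": cade.build_slab(norm, c), "label": 1,
                 "reg": np.array([n.diameter_mm / 2, 0, 0, 0], np.float32)}
            )
    if not any(e["label"] == 0 for e in refine_examples):
        head = None  # degenerate: no negatives to learn from
    else:
        head = cade.train_refine_head(
            refine_examples, seed=_stage_seed(cfg, "refine"),
            n_steps=cfg.refine_steps,
        )

    # ---- Stage 1 evaluation on the test cohort ---------------------
    detections = []
    seg_dices = []
    for s in test:
        pred, cands = _detect_scan(seg_model, head, s, cfg)
        detections.extend(cands)
        post = seg.postprocess_nodule_mask(pred.prob_map)
        seg_dices.append(
            seg.seg_metrics(post, s.volume.copy_with(s.nodule_mask_gt.data > 0))
        )
    det_path = os.path.join(cfg.out_dir, "detections.csv")
    cade.detections_frame(detections).to_csv(det_path, index=False)
    report["artifacts"]["detections"] = det_path

    ann_df = phantom.annotations_frame(test)
    ann = evaluate.annotations_by_series(ann_df)
    froc_res = evaluate.froc(detections, ann, n_scans=len(test))
    strat = evaluate.stratified_sensitivity(detections, ann_df, len(test))
    report["stages"]["segmentation"] = {
        "mean_dice": float(np.mean([d["dice"] for d in seg_dices])),
        "mean_iou": float(np.mean([d["iou"] for d in seg_dices])),
    }
    report["stages"]["detection"] = {
        "n_scans": len(test),
        "cpm": froc_res.cpm,
        "operating_points": list(froc_res.operating_points),
        "sensitivities": froc_res.sensitivities,
        "sensitivity_at_1fps": froc_res.sensitivities[3],
        "stratified": strat.to_dict(orient="records"),
    }

    # ---- Stage 2: malignancy classification ------------------------
    train_ex = _nodule_examples(train, cfg.cube_size)
    test_ex = _nodule_examples(test, cfg.cube_size)
    clf = cadx.train_classifier(
        train_ex, cfg.cadx, seed=_stage_seed(cfg, "cadx"),
        n_steps=cfg.cadx_steps,
    )
    clf.set_stochastic(False)

    def _logits(exs):
        cubes = np.stack([e["cube"] for e in exs])
        rads = np.stack([e["radiomics"] for e in exs])
        lg, _ = cadx.predict_logit(clf, cubes, rads)
        return lg

    logits_tr, y_tr = _logits(train_ex), np.array([e["label"] for e in train_ex])
    logits_te, y_te = _logits(test_ex), np.array([e["label"] for e in test_ex])
    roc = evaluate.roc_pr_metrics(expit(logits_te), y_te)
    report["stages"]["cadx"] = {
        "roc_auc": roc.roc_auc, "pr_auc": roc.pr_auc,
        "accuracy": roc.accuracy, "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "youden_threshold": roc.youden_threshold,
        "n_train_nodules": len(train_ex), "n_test_nodules": len(test_ex),
    }
    pred_path = os.path.join(cfg.out_dir, "predictions.csv")
    import pandas as pd

    pd.DataFrame(
        {
            "seriesuid": [e["series_id"] for e in test_ex],
            "nodule_id": [e["nodule_id"] for e in test_ex],
            "logit": logits_te,
            "prob": expit(logits_te),
            "label": y_te,
        }
    ).to_csv(pred_path, index=False)
    report["artifacts"]["predictions"] = pred_path

    # ---- calibration (fitted on the training fold) ------------------
    cal = calibrate.calibration_report(
        logits_te, y_te, fit_logits=logits_tr, fit_labels=y_tr
    )
    dca = cal["decision_curve_post"]
    report["stages"]["calibration"] = {
        "temperature": cal["temperature"],
        "ece_pre": cal["ece_pre"], "ece_post": cal["ece_post"],
        "brier_pre": cal["brier_pre"], "brier_post": cal["brier_post"],
        "nll_pre": cal["nll_pre"], "nll_post": cal["nll_post"],
        "mean_net_benefit": float(dca["net_benefit_model"].mean()),
    }
    dca_path = os.path.join(cfg.out_dir, "decision_curve.csv")
    dca.to_csv(dca_path, index=False)
    rel_path = os.path.join(cfg.out_dir, "reliability.csv")
    cal["reliability"].to_csv(rel_path, index=False)
    report["artifacts"]["decision_curve"] = dca_path
    report["artifacts"]["reliability"] = rel_path

    # ---- scan-level risk -------------------------------------------
    tm = calibrate.TemperatureModel(cal["temperature"])
    risks = {}
    for s in test:
        probs = [
            float(tm.predict_proba(l))
            for l, e in zip(logits_te, test_ex)
            if e["series_id"] == s.series_id
        ]
        risks[s.series_id] = cadx.aggregate_scan_risk(probs, "topK", cfg.top_k)
    report["stages"]["scan_risk"] = risks

    report_path = os.path.join(cfg.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["artifacts"]["report"] = report_path
    return report


def demo_config(seed: int = 0, out_dir: str = "runs/demo") -> RunConfig:
    """Scaled-down study conditions for the end-to-end phantom demo:
    30 scans of 96^3 voxels at 1 mm, easy solid nodules >= 8 mm whose
    malignancy is deterministically tied to spiculated/lobulated shape
    (spiculated-malignant vs. smooth-benign), and tiny models sized for a
    single CPU."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        n_train=20,
        n_test=10,
        phantom=phantom.PhantomConfig(
            grid_shape=(96, 96, 96),
            diameter_mm=(8.0, 14.0),
            stratum_mix=(0.0, 0.5, 0.5),
            attenuation_mix={"solid": 1.0, "part_solid": 0.0, "ground_glass": 0.0},
            attribute_link_scale=None,
            nodules_per_scan=(2, 4),
        ),
        seg_steps=350,
        refine_steps=1200,
        cadx_steps=400,
    )


def make_report(out_dir: str) -> str:
    """Human-readable stage summary regenerated from saved artifacts."""
    path = os.path.join(out_dir, "report.json")
    missing = [p for p in [path] if not os.path.exists(p)]
    if missing:
        return "MISSING ARTIFACTS:\n" + "\n".join(f"  {m}" for m in missing)
    with open(path) as fh:
        rep = json.load(fh)
    lines = [f"segcadx run report (seed {rep['seed']})", "=" * 40]
    st = rep["stages"]
    s = st.get("segmentation", {})
    lines.append(f"Stage 0 segmentation: Dice {s.get('mean_dice', float('nan')):.3f} "
                 f"IoU {s.get('mean_iou', float('nan')):.3f}")
    d = st.get("detection", {})
    cpm = d.get("cpm", 0.0)
    lines.append(f"Stage 1 detection:    CPM {cpm:.3f} "
                 f"sens@1FP/scan {d.get('sensitivity_at_1fps', 0.0):.3f}"
                 + ("   [WARNING: no detections]" if cpm == 0 else ""))
    c = st.get("cadx", {})
    lines.append(f"Stage 2 malignancy:   ROC-AUC {c.get('roc_auc', float('nan')):.3f} "
                 f"PR-AUC {c.get('pr_auc', float('nan')):.3f} "
                 f"acc {c.get('accuracy', float('nan')):.3f}")
    k = st.get("calibration", {})
    lines.append(f"Calibration:          T {k.get('temperature', float('nan')):.3f} "
                 f"ECE {k.get('ece_pre', float('nan')):.3f}->{k.get('ece_post', float('nan')):.3f} "
                 f"Brier {k.get('brier_post', float('nan')):.3f}")
    lines.append("Artifacts:")
    for name, p in sorted(rep.get("artifacts", {}).items()):
        lines.append(f"  {name}: {p}" + ("" if os.path.exists(p) else "  [missing]"))
    return "\n".join(lines)
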