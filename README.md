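# segcadx

Segmentation-guided detection and calibrated malignancy risk prediction
for pulmonary nodules in low-dose chest CT, exercised end to end on
synthetic phantoms.

Lung-cancer screening pipelines face two coupled tasks: **CADe** —
finding nodules in a volumetric scan while keeping false positives per
scan low — and **CADx** — turning each finding into a malignancy
probability a clinician can act on. `segcadx` implements a complete
desk-scale version of a modern two-stage design, for researchers who
want the full machinery (losses, matching rules, FROC/CPM protocol,
calibration and decision-curve analysis, significance tests) in tested,
inspectable NumPy/SciPy code, with a synthetic-phantom generator so that
every stage is trainable and measurable without any external dataset.

## The pipeline

**Stage 0/1 (detection).** A residual 3D U-Net segments nodule voxels
from 1 mm isotropic, HU-windowed ([−1000, 400] → [0, 1]), lung-masked
volumes, trained with a composite loss

    L_seg = L_Dice + λ·L_BCE + α·L_Focal,

where DSC(P, G) = 2ΣPᵢGᵢ / (ΣPᵢ² + ΣGᵢ²), foreground voxels carry 3:1
weight, and nodule-centred patches are sampled with two nodule-free lung
patches per positive (2:1). Probability maps are thresholded at 0.35,
components below 5 mm equivalent diameter removed, and local maxima
pruned by 5 mm NMS become candidates. A lightweight 2.5D head (a stack
of 5 adjacent axial slices) rescores each candidate (cross-entropy plus
smooth-ℓ1 regression of radius and sub-voxel offsets,
L_Det = αL_cls + βL_loc). A detection is a true positive iff its centre
falls within the annotated nodule radius; duplicates of a hit nodule are
ignored. FROC analysis reports sensitivity at FP/scan ∈
{0.125, 0.25, 0.5, 1, 2, 4, 8}; their mean is the CPM.

**Stage 2 (diagnosis).** Each candidate's 32³ crop is encoded by two
streams — a densely connected 3D convolutional encoder and a
hierarchical windowed self-attention encoder — whose embedding z is
late-fused with a radiomics vector r (intensity statistics, volume,
surface area, sphericity π^{1/3}(6V)^{2/3}/A, compactness, A/V) as
f = [z‖r], then mapped to a malignancy probability plus auxiliary
spiculation/lobulation/subtlety estimates
(L_CADx = L_bin + Σ_j β_j L_attr,j, β_j ∈ [0.05, 0.1]). Monte Carlo
dropout gives per-nodule uncertainty; top-K or attention pooling gives a
scan-level risk. Temperature scaling (T fitted by NLL on held-out data)
calibrates the probabilities; ECE, Brier score, reliability tables and
decision-curve net benefit NB = TP/n − (FP/n)·p_t/(1−p_t) quantify
reliability and clinical utility; DeLong tests and patient-level
bootstrap CIs cover significance.

The trainable networks run on a small reverse-mode autodiff engine over
NumPy (`segcadx.nn`) — gradient-checked against finite differences —
so the whole package needs only the scientific Python stack.

## Worked example

```python
from segcadx.pipeline import demo_config, run_end_to_end, make_report

report = run_end_to_end(demo_config(seed=3, out_dir="runs/demo"))
print(make_report("runs/demo"))
```

This generates 20 training + 10 test phantoms (96³ voxels at 1 mm; two
ellipsoidal lungs at −850 HU inside a body with rib-like arcs; vessel
tubes; solid 8–14 mm nodules whose malignancy follows their
spiculation/lobulation), trains the tiny U-Net, refinement head and
hybrid classifier, and evaluates on the held-out cohort. Output:

```
segcadx run report (seed 3)
========================================
Stage 0 segmentation: Dice 0.907 IoU 0.833
Stage 1 detection:    CPM 0.992 sens@1FP/scan 1.000
Stage 2 malignancy:   ROC-AUC 0.986 PR-AUC 0.990 acc 0.912
Calibration:          T 0.212 ECE 0.203->0.084 Brier 0.062
```

Reading it: the postprocessed segmentation masks overlap ground truth at
Dice 0.91; sweeping the detector's score threshold, every test nodule is
found at an operating point costing one false positive per scan, and the
mean sensitivity over the seven FROC operating points (CPM) is 0.99; the
classifier separates malignant from benign test nodules with ROC-AUC
0.99. Temperature scaling here *sharpens* the probabilities (T ≈ 0.21):
the heavily regularised classifier is underconfident on these easy
phantoms, and calibration reduces the expected calibration error from
0.203 to 0.084 accordingly. Artifacts
(annotation/detection/prediction CSVs, reliability and decision-curve
tables, `report.json`) land in `runs/demo/`.

A CLI wraps the same calls: `segcadx simulate`, `segcadx run-all --seed 3
--out runs/demo`, `segcadx report runs/demo`, `segcadx
evaluate-detections`.

## Layout

| module | contents |
| --- | --- |
| `segcadx.phantom` | synthetic LDCT volumes, ground truth, annotation CSVs, patient splits |
| `segcadx.preprocess` | isotropic resampling, HU windowing, lung masking |
| `segcadx.seg` | residual 3D U-Net, Dice/BCE/focal losses, patch sampling, mask postprocessing, Dice/IoU/HD95 |
| `segcadx.cade` | local-maxima candidates, NMS, 2.5D refinement, detection losses, hit-criterion matching |
| `segcadx.cadx` | radiomics, hybrid dual-stream classifier, MC-dropout, scan-risk pooling, label harmonisation |
| `segcadx.calibrate` | temperature scaling, ECE/Brier/NLL, reliability tables, decision curves |
| `segcadx.evaluate` | FROC/CPM, stratified sensitivity, ROC/PR, DeLong, patient-level bootstrap |
| `segcadx.pipeline` | end-to-end orchestration, run reports |
| `segcadx.nn` | NumPy autodiff + conv/attention building blocks |

See `docs/methods.md` for the modelling assumptions, defaults and
limitations.
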