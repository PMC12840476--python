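# Methods

`segcadx` implements a two-stage pipeline for pulmonary-nodule analysis in
low-dose chest CT — voxelwise segmentation-guided candidate detection
(CADe) followed by calibrated malignancy risk prediction (CADx) — together
with the evaluation protocol customary for this task (FROC/CPM, ROC/PR,
calibration and decision-curve analysis, DeLong and bootstrap inference).
Because the package is exercised end to end on synthetic phantoms rather
than clinical scans, this note records exactly what is modelled, which
constants matter, and what passing the test suite does and does not show.

## The phantom model

Each phantom is a 3D volume in Hounsfield units on an axis-aligned grid
(default 96³ voxels at 1 mm isotropic spacing; array index order (x, y, z)
with `world = origin + index · spacing`, matching the annotation-CSV
convention). The scene contains:

- a soft-tissue body ellipsoid (~40 HU) surrounded by air (−1000 HU),
  with high-density shell bands (~700 HU) standing in for ribs;
- two lung ellipsoids at −850 HU (the ground-truth lung mask);
- vessels as random-walk tubes of radius 1–2 mm at ~+50 HU inside the
  lungs (per-lung count `vessel_density`, default 5) — these are the
  principal source of detector false positives, exactly as vessel
  fragments are in clinical CADe;
- nodules with controlled diameter and attenuation class: solid
  (uniform −50…+100 HU), ground-glass (−700…−500 HU), or part-solid
  (ground-glass halo with a solid core at 55 % of the radius);
- additive Gaussian noise (`noise_sd_hu`, default 20 HU).

Nodule diameter is sampled by stratum (≤6 mm, 6–10 mm, >10 mm;
`stratum_mix`, default uniform) and then uniformly within the stratum, so
stratified sensitivity tables are exercised by construction. The rasterizer
draws a sphere plus thin radial spikes (spiculation) and offset lobes
(lobulation), then rescales the core once so that the equivalent-sphere
diameter of the digitized mask matches the nominal diameter within one
voxel despite the appendage volume.

**Malignancy generation.** Shape attributes come first: a latent
aggressiveness bit (rate `malignant_fraction`) selects the attribute
regime (spiculation ~N(4.0, 0.6) and lobulation ~N(3.8, 0.6) for
aggressive nodules; N(1.8, 0.6)/N(2.0, 0.6) otherwise, clipped to [1, 5]).
The label is then drawn from a logistic link on the attribute contrast
u = 0.6·(spiculation−3) + 0.4·(lobulation−3), i.e.
p(malignant) = σ(s·u) with `attribute_link_scale` s = 3.0 by default.
The rendered morphology (spike and lobe counts) follows the attributes,
not the label, so a classifier must genuinely read shape from the image;
an oracle scoring the true attributes attains ROC-AUC ≈ 0.96 at the
default scale (measured once on 20 000 draws), which sets the ceiling for
any image-based classifier under the default conditions.
`attribute_link_scale=None` makes the link deterministic (malignant iff
u > 0); the end-to-end demo uses this "spiculated-malignant vs
smooth-benign" regime. Four simulated readers score each nodule by
rounding a label-consistent latent score with ±1 integer noise, resampled
(bounded) so consensus averaging never contradicts the generating label.

**What the phantoms do not emulate:** airway trees, pleural attachment,
scanner kernels and dose-dependent noise texture, DICOM geometry,
inter-reader segmentation variability, and the long-tailed hard negatives
of clinical screening (scars, atelectasis). Passing the end-to-end
acceptance run therefore shows the pipeline's machinery is correct and
trainable, not that its operating points transfer to LIDC/LUNA-class data.

## Preprocessing

Volumes are resampled to 1 mm isotropic (trilinear for intensities,
nearest-neighbour for masks), clipped to the diagnostic window
[−1000, 400] HU, rescaled linearly to [0, 1], and restricted to the lung
fields (out-of-lung voxels set to 0, the windowed air level). Lung-mask
post-processing thresholds a probability map at 0.5 and applies
morphological closing with a 3-voxel ball (the smallest element bridging
vessel-induced gaps at 1 mm) followed by hole filling. The pipeline uses
the phantom's ground-truth lung mask by default; a trainable lung
segmenter can reuse the same U-Net machinery.

## Stage 1: segmentation-guided detection

A residual 3D U-Net (2×2×2 max-pooled encoder, 2×2×2 up-convolved
decoder, identity/projection skips, optional deep supervision with weights
½, ¼, … per decoder level) produces a voxelwise nodule probability map.
The training objective is a single configurable composite

    L = L_Dice + λ·L_BCE + α_focal·L_Focal,   defaults λ = 1, α_focal = 1,

with foreground voxels weighted `fg_weight`:1 (default 3:1) in the Dice
and focal terms and focusing exponent γ = 2 (γ is not standardised
anywhere in the literature for this setting; 2 is the common default).
Setting λ = 0 or α_focal = 0 recovers the pure Dice+focal or Dice+BCE
variants. The metric-facing Dice uses smoothing ε = 1e−5 (defining the
empty/empty case as 1); the training path computes Dice per sample with
smoothing 1.0, which keeps the term well-behaved on nodule-free patches.

Patches (default 64³; the CPU demo uses 24³) are sampled nodule-centred
with jitter, plus exactly two nodule-free lung patches per positive (2:1).
Batches are stratified to contain at least one positive. Optimisation is
AdamW with a 25-step linear learning-rate warmup, global gradient-norm
clipping at 5.0, and a single cosine decay cycle; a cosine schedule with
warm restarts is available but not used by default. Both safeguards exist
because this small-batch problem is fragile early in training: fresh Adam
second-moment estimates (and, with restarts, the lr jump against stale
ones) can saturate the network into a dead all-background solution from
which sigmoid gradients cannot recover. The best-validation-Dice
checkpoint is returned.

Mask post-processing thresholds at 0.35, removes 26-connected components
with equivalent-sphere diameter below 5 mm, and closes with a 1-voxel
ball; the procedure is idempotent. Candidates are 26-neighbourhood local
maxima converted to world mm, pruned by greedy distance-based NMS (5 mm;
spherical candidates make IoU-NMS pointless), with radii initialised from
the thresholded component. A 2.5D refinement head (three strided 2D
convolutions over a 5-slice, 32 mm axial stack) rescores each candidate
and regresses radius (mm) and sub-voxel centre offsets (voxels); offsets
are clipped to the slab's voxel scale implicitly by training targets.
Detection losses follow the standard forms: two-class cross-entropy,
smooth-ℓ1 averaged over the four regression dimensions,
L_Det = w_cls·L_cls + w_loc·L_loc, and the joint Stage-1 objective
L_CADe = L_seg + ϕ1·L_cls + ϕ2·L_reg (defaults w_cls = w_loc = ϕ1 = 1,
ϕ2 = 0.5; none of these weights is pinned by published values).
Hard-negative mining appends the top-N highest-scored false positives to
the training pool. Matching uses the centre-within-radius criterion
(boundary inclusive); the highest-scoring detection claims each nodule and
duplicates of a hit nodule are ignored, not false positives (the LUNA16
evaluation convention).

## Stage 2: hybrid malignancy classification

Each candidate yields a fixed 32³ crop at 1 mm. Two streams encode it: a
densely connected 3D convolutional encoder (local texture) and a two-stage
hierarchical windowed self-attention encoder (4 mm patch embedding,
attention within 4³-token windows, 2× patch merging, then global
attention) for long-range context — the smallest configuration honouring
both architectural ideas at this input size. A handcrafted radiomics
vector r (in-mask intensity mean/sd/min/max/p25/p75, volume, surface
area, sphericity, compactness, surface-to-volume) is late-fused with the
deep embedding z as f = [z‖r] and passed through an MLP trunk to a
sigmoid malignancy head and three attribute regression heads
(spiculation, lobulation, subtlety, rescaled to [0, 1]). The loss is
L_CADx = L_bin + Σ_j β_j·L_attr,j with smooth-ℓ1 attribute terms and
β = (0.1, 0.1, 0.05), inside the recommended 0.05–0.1 band. Either
stream and the radiomics input can be disabled to realise the ablation
arms.

Surface area comes from a marching-cubes mesh rather than boundary-face
counting: face counting overstates oblique surfaces by ~1.5×, which would
push digitized-sphere sphericity to ~0.67, far outside the documented
(0, 1.05] contract; the mesh estimator keeps it at ~0.9 with a residual
staircase bias that does not grow with size. Radiomics are invariant to
intensities outside the mask by construction.

Regularisation matters more than capacity at phantom scale: training uses
random axis permutations/flips of the cube (valid because the grid is
isotropic and radiomics are orientation-invariant), dropout 0.3 both on
the deep embedding before fusion and in the trunk (the learned features
are the high-variance half of the fusion), and z-scored radiomics using
training-set statistics stored on the model. Dropout layers stay active
on request at inference for Monte Carlo uncertainty (mean and sd of n
stochastic passes, default 20, seeded). Scan-level risk is top-K pooling
(mean of the K = 3 highest candidate probabilities) or attention pooling
(softmax-weighted mean with scores proportional to the probabilities);
scans without candidates get risk 0 (no evidence of malignancy).
Consensus labels: mean reader score < 3 benign, > 3 malignant, exactly 3
excluded from training and evaluation.

## Calibration and clinical utility

Temperature scaling divides held-out logits by a scalar T fitted by
bounded 1-D search (T ∈ [0.05, 20]) minimising the negative
log-likelihood — a smooth surrogate for ECE, which is piecewise constant
and unstable to optimise directly; ECE (15 equal-width bins) is reported
before and after instead. Scaling preserves ranking, so ROC-AUC is
bit-identical by construction. Net benefit is
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t), reported against treat-all and
treat-none over the clinically actionable grid 0.10 ≤ p_t ≤ 0.40.
In the pipeline, T is fitted on the training fold and applied to the test
fold.

## Evaluation protocol

FROC analysis sweeps every detection score as a threshold, recomputes
per-scan matching at each, and reads sensitivity at FP/scan ∈
{0.125, 0.25, 0.5, 1, 2, 4, 8} off the stepwise curve (the value at the
largest achieved FP/scan not exceeding the operating point; stepwise
rather than linear interpolation because it is conservative and exactly
checkable against an exhaustive oracle). CPM is the mean of the seven
sensitivities. Size strata use ≤6 / (6, 10] / >10 mm (the small class is
"6 mm or less"). ROC-AUC is the rank statistic with half-credit ties;
PR-AUC uses stepwise interpolation; the Youden threshold comes from an
exhaustive sweep of unique scores. The DeLong test uses placement-value
covariances and reports a one-sided p for AUC_a > AUC_b, with a
degenerate-variance flag (identical scores give p = 0.5 by convention).
Bootstrap confidence intervals resample patients (scan IDs) with
replacement, percentile method, 2000 draws by default (1000 is also in
circulation; the count is a parameter), redrawing resamples on which the
metric is undefined. Fold-level comparisons use a paired t-test across
the cross-validation folds.

## The scaled-down end-to-end study

`segcadx.pipeline.demo_config` fixes the study conditions for the
CPU-scale demonstration: 20 training + 10 test phantoms of 96³ voxels,
solid nodules of 8–14 mm (2–4 per scan), deterministic shape→label link,
a depth-2/8-channel U-Net trained 350 steps on 24³ patches (batch 3), a
250-step refinement head fed by candidates from 8 training scans plus
ground-truth-centred positives, and a 400-step hybrid classifier. These
problem sizes are the package's chosen desk-scale conditions; one full
run takes roughly ten minutes on a single CPU core. Train and test
cohorts come from disjoint seed streams, which enforces patient-level
separation; a single global seed fans out to per-stage seeds by fixed
offsets, so each stage is reproducible in isolation and a whole run is
bit-reproducible.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [1e−6, 1 − 1e−6] ahead of logarithms via
  an affine squeeze of the sigmoid (which preserves gradients, unlike a
  hard clip).
- Empty/empty masks: Dice = IoU = 1, HD95 = 0; one-sided emptiness gives
  Dice = IoU = 0 and HD95 = ∞.
- Ties in NMS and matching break by score, then input order; maxpool
  gradient splits evenly across tied entries.
- Nodule placement retries are bounded (200); exhaustion raises a
  generation error rather than silently dropping the nodule.
- The networks run in float32 throughout; gradient correctness is
  enforced by finite-difference tests rather than assumed.

## Known limitations

- The phantom's difficulty is set by geometry and noise levels, not by a
  fit to any clinical dataset; absolute metric values from the demo are
  not comparable to published benchmark numbers.
- The windowed-attention stream is the minimal two-stage hierarchy; it
  under-uses its design at 32³ inputs and exists to make the dual-stream
  and ablation structure real, not to be competitive alone.
- The mesh-based sphericity estimator retains a ~8 % staircase bias that
  does not vanish with nodule size; comparisons between nodules are
  unaffected, absolute sphericities are slightly conservative.
- `froc` recomputes matching at every threshold (O(thresholds ×
  detections)); fine at desk scale, quadratic in candidate count.
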