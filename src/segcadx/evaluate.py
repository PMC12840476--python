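"""Detection and classification evaluation.

Detection uses the free-response ROC protocol: the score threshold is
swept over all detection scores; at each threshold per-scan matching
yields sensitivity vs. false positives per scan, and the competition
performance metric (CPM) is the mean sensitivity at FP/scan in
{0.125, 0.25, 0.5, 1, 2, 4, 8}, read off the stepwise curve (the value
at the largest achieved FP/scan not exceeding each operating point).
Classification reports ROC-AUC (rank statistic), PR-AUC, and operating
points; significance machinery covers the DeLong paired-AUC test and
patient-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .cade import Candidate, match_detections

FROC_OPERATING_POINTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class FROCResult:
    operating_points: tuple = FROC_OPERATING_POINTS
    sensitivities: list[float] = field(default_factory=list)
    cpm: float = 0.0
    curve_fps: np.ndarray = field(default_factory=lambda: np.array([]))
    curve_sens: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ROCReport:
    roc_auc: float
    pr_auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    youden_threshold: float
    youden_j: float


# ----------------------------------------------------------------------
# FROC / CPM
# ----------------------------------------------------------------------

AnnotationsBySeries = dict[str, list[tuple[np.ndarray, float]]]


def annotations_by_series(df: pd.DataFrame) -> AnnotationsBySeries:
    """Group an annotation table (seriesuid, coordX/Y/Z, diameter_mm)
    into per-scan (centre, radius) lists."""
    out: AnnotationsBySeries = {}
    for r in df.itertuples():
        out.setdefault(str(r.seriesuid), []).append(
            (np.array([r.coordX, r.coordY, r.coordZ]), r.diameter_mm / 2.0)
        )
    return out


def froc(
    detections: list[Candidate],
    annotations: AnnotationsBySeries,
    n_scans: int,
    operating_points=FROC_OPERATING_POINTS,
) -> FROCResult:
    """FROC analysis with per-scan matching at every score threshold."""
    if n_scans <= 0:
        raise ValueError("n_scans must be positive")
    n_nodules = sum(len(v) for v in annotations.values())
    by_series: dict[str, list[Candidate]] = {}
    for d in detections:
        by_series.setdefault(d.series_id, []).append(d)
    thresholds = sorted({d.score for d in detections}, reverse=True)
    fps_list, sens_list = [0.0], [0.0]  # trivial empty-detection point
    for t in thresholds:
        tp = fp = 0
        for sid in set(by_series) | set(annotations):
            dets = [d for d in by_series.get(sid, []) if d.score >= t]
            res = match_detections(dets, annotations.get(sid, []))
            tp += res.tp
            fp += res.fp
        fps_list.append(fp / n_scans)
        sens_list.append(tp / n_nodules if n_nodules else 0.0)
    fps = np.array(fps_list)
    sens = np.array(sens_list)
    order = np.argsort(fps, kind="stable")
    fps, sens = fps[order], sens[order]
    sens = np.maximum.accumulate(sens)  # stepwise envelope
    sensitivities = []
    for f in operating_points:
        achieved = fps <= f
        sensitivities.append(float(sens[achieved][-1]) if achieved.any() else 0.0)
    return FROCResult(
        operating_points=tuple(operating_points),
        sensitivities=sensitivities,
        cpm=float(np.mean(sensitivities)),
        curve_fps=fps,
        curve_sens=sens,
    )


def sensitivity_from_counts(tp: int, fn: int) -> float:
    """Sensitivity as a percentage, one decimal: 100*tp/(tp+fn)."""
    if tp + fn <= 0:
        raise ValueError("sensitivity undefined for tp+fn = 0")
    return round(100.0 * tp / (tp + fn), 1)


SIZE_STRATA = ("<=6 mm", "6-10 mm", ">10 mm")


def stratify_by_size(diameters_mm) -> np.ndarray:
    """Stratum index per nodule: 1 for <=6 mm, 2 for (6, 10] mm, 3 for
    >10 mm."""
    d = np.asarray(diameters_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return np.where(d <= 6.0, 1, np.where(d <= 10.0, 2, 3))


def stratified_sensitivity(
    detections: list[Candidate],
    annotations_df: pd.DataFrame,
    n_scans: int,
    fp_per_scan: float = 1.0,
) -> pd.DataFrame:
    """Per-size-stratum sensitivity at an operating point of
    ``fp_per_scan`` false positives per scan.

    The score threshold is chosen as the smallest one whose overall
    FP/scan does not exceed the operating point; matching is then redone
    per stratum at that threshold.
    """
    ann = annotations_by_series(annotations_df)
    thresholds = sorted({d.score for d in detections}, reverse=True)
    chosen = None
    for t in thresholds:
        fp = 0
        for sid in set(ann) | {d.series_id for d in detections}:
            dets = [d for d in detections if d.series_id == sid and d.score >= t]
            fp += match_detections(dets, ann.get(sid, [])).fp
        if fp / n_scans <= fp_per_scan:
            chosen = t
        else:
            break
    rows = []
    strata = stratify_by_size(annotations_df["diameter_mm"].to_numpy())
    annotations_df = annotations_df.assign(_stratum=strata)
    for s, name in enumerate(SIZE_STRATA, start=1):
        tp = fn = fp = 0
        for sid in set(ann):
            sub = annotations_df[
                (annotations_df.seriesuid == sid) & (annotations_df._stratum == s)
            ]
            nods = [
                (np.array([r.coordX, r.coordY, r.coordZ]), r.diameter_mm / 2)
                for r in sub.itertuples()
            ]
            dets = [
                d for d in detections
                if d.series_id == sid and chosen is not None and d.score >= chosen
            ]
            res = match_detections(dets, nods)
            tp += res.tp
            fn += res.fn
        rows.append(
            {
                "stratum": name,
                "tp": tp,
                "fn": fn,
                "sensitivity_pct": sensitivity_from_counts(tp, fn) if tp + fn else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# ROC / PR
# ----------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC-AUC as the rank statistic P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_pr_metrics(probs, labels, threshold: float = 0.5) -> ROCReport:
    """Classification report: rank-statistic ROC-AUC, stepwise PR-AUC,
    operating point at ``threshold``, and the Youden-optimal threshold
    found by exhaustive sweep over the unique scores."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(probs, labels)
    pr = float(average_precision_score(labels, probs))
    pred = probs >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    sens = tp / max(labels.sum(), 1)
    spec = tn / max((labels == 0).sum(), 1)
    best_j, best_t = -1.0, 0.5
    for t in np.unique(probs):
        p = probs >= t
        se = (p & (labels == 1)).sum() / labels.sum()
        sp = (~p & (labels == 0)).sum() / (labels == 0).sum()
        j = se + sp - 1
        if j > best_j:
            best_j, best_t = float(j), float(t)
    return ROCReport(
        roc_auc=auc,
        pr_auc=pr,
        accuracy=float((pred == labels).mean()),
        sensitivity=float(sens),
        specificity=float(spec),
        threshold=threshold,
        youden_threshold=best_t,
        youden_j=best_j,
    )


# ----------------------------------------------------------------------
# significance machinery
# ----------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i]: fraction of negatives each positive outranks (ties half)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> dict:
    """One-sided DeLong test of H1: AUC_a > AUC_b on paired scores.

    Returns auc_a, auc_b, the variance of the difference, z, p_value, and
    a ``degenerate`` flag when the variance estimate collapses to zero
    (identical scores give p = 0.5 by convention).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("delong_test needs both classes")
    auc_a = roc_auc(scores_a, labels)
    auc_b = roc_auc(scores_b, labels)
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-14:
        return {
            "auc_a": auc_a, "auc_b": auc_b, "var": float(max(var, 0.0)),
            "z": 0.0, "p_value": 0.5 if auc_a == auc_b else (0.0 if auc_a > auc_b else 1.0),
            "degenerate": True,
        }
    z = (auc_a - auc_b) / np.sqrt(var)
    return {
        "auc_a": auc_a, "auc_b": auc_b, "var": float(var),
        "z": float(z), "p_value": float(stats.norm.sf(z)), "degenerate": False,
    }


def bootstrap_ci(
    metric_fn,
    data: pd.DataFrame,
    group_col: str = "seriesuid",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    max_retries_factor: int = 10,
) -> dict:
    """Patient-level bootstrap percentile CI of ``metric_fn(data)``.

    Scans (``group_col`` values) are resampled with replacement; a
    resample on which the metric raises is redrawn (bounded retries,
    counted in ``n_redrawn``).
    """
    groups = data[group_col].to_numpy()
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two patients to bootstrap")
    idx_of = {g: np.flatnonzero(groups == g) for g in uniq}
    rng = np.random.default_rng(seed)
    point = float(metric_fn(data))
    vals = []
    redrawn = 0
    attempts_left = max_retries_factor * n_boot
    while len(vals) < n_boot and attempts_left > 0:
        attempts_left -= 1
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        rows = np.concatenate([idx_of[g] for g in chosen])
        try:
            vals.append(float(metric_fn(data.iloc[rows])))
        except Exception:
            redrawn += 1
    if len(vals) < n_boot:
        raise RuntimeError("bootstrap failed: metric undefined on too many resamples")
    vals = np.array(vals)
    return {
        "point": point,
        "mean": float(vals.mean()),
        "lo95": float(np.percentile(vals, 100 * alpha / 2)),
        "hi95": float(np.percentile(vals, 100 * (1 - alpha / 2))),
        "n_redrawn": redrawn,
    }


def paired_fold_ttest(metrics_a, metrics_b) -> dict:
    """Paired t-test over per-fold metrics (e.g. the 5 CV folds)."""
    t, p = stats.ttest_rel(metrics_a, metrics_b)
    return {"t": float(t), "p_value": float(p)}
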