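"""Independent brute-force reference implementations used to cross-check
the package's evaluation metrics.  Deliberately naive: plain loops and
exhaustive enumeration, structured nothing like the library code."""

import numpy as np


def auc_pairwise(scores, labels):
    """ROC-AUC by exhaustive pair enumeration with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ece_loop(probs, labels, n_bins=15):
    """ECE by explicit per-bin loops over equal-width bins."""
    probs = list(probs)
    labels = list(labels)
    n = len(probs)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = [
            i for i, p in enumerate(probs)
            if (lo <= p < hi) or (b == n_bins - 1 and p == 1.0)
        ]
        if not members:
            continue
        mean_p = sum(probs[i] for i in members) / len(members)
        pos = sum(labels[i] for i in members) / len(members)
        total += len(members) / n * abs(mean_p - pos)
    return total


def net_benefit_counts(probs, labels, p_t):
    """Net benefit from raw TP/FP counting."""
    tp = sum(1 for p, y in zip(probs, labels) if p >= p_t and y == 1)
    fp = sum(1 for p, y in zip(probs, labels) if p >= p_t and y == 0)
    n = len(labels)
    return tp / n - (fp / n) * p_t / (1 - p_t)


def _match_scan(dets, nodules):
    """Greedy centre-in-radius matching; returns (tp, fp).

    dets: list of (center xyz, score); nodules: list of (center, radius).
    Highest score claims a nodule first; duplicates of a hit nodule are
    ignored; detections outside every nodule are false positives.
    """
    taken = set()
    tp = fp = 0
    for c, s in sorted(dets, key=lambda d: -d[1]):
        inside = [
            j for j, (nc, r) in enumerate(nodules)
            if np.sqrt(sum((a - b) ** 2 for a, b in zip(c, nc))) <= r
        ]
        free = [j for j in inside if j not in taken]
        if free:
            best = min(
                free,
                key=lambda j: np.sqrt(
                    sum((a - b) ** 2 for a, b in zip(c, nodules[j][0]))
                ),
            )
            taken.add(best)
            tp += 1
        elif not inside:
            fp += 1
    return tp, fp


def froc_exhaustive(dets_by_scan, nodules_by_scan, n_scans,
                    operating_points=(0.125, 0.25, 0.5, 1, 2, 4, 8)):
    """FROC sensitivities/CPM by enumerating every score threshold and
    picking, per operating point, the best sensitivity among thresholds
    whose FP/scan does not exceed it."""
    n_nodules = sum(len(v) for v in nodules_by_scan.values())
    all_scores = sorted({s for dets in dets_by_scan.values() for _, s in dets})
    curve = [(0.0, 0.0)]
    for t in all_scores:
        tp_tot = fp_tot = 0
        for sid in set(dets_by_scan) | set(nodules_by_scan):
            dets = [d for d in dets_by_scan.get(sid, []) if d[1] >= t]
            tp, fp = _match_scan(dets, nodules_by_scan.get(sid, []))
            tp_tot += tp
            fp_tot += fp
        curve.append((fp_tot / n_scans, tp_tot / n_nodules if n_nodules else 0.0))
    sens_at = []
    for f in operating_points:
        feasible = [s for fp, s in curve if fp <= f]
        sens_at.append(max(feasible) if feasible else 0.0)
    return sens_at, float(np.mean(sens_at))


def random_detection_instance(rng, max_scans=5, max_dets=10):
    """A random small detection problem on a 1D-ish geometry."""
    n_scans = int(rng.integers(1, max_scans + 1))
    dets_by_scan, nodules_by_scan = {}, {}
    for i in range(n_scans):
        sid = f"s{i}"
        n_nod = int(rng.integers(0, 4))
        nodules_by_scan[sid] = [
            (rng.uniform(0, 100, size=3), float(rng.uniform(2, 8)))
            for _ in range(n_nod)
        ]
        n_det = int(rng.integers(0, max_dets + 1))
        dets = []
        for _ in range(n_det):
            if nodules_by_scan[sid] and rng.random() < 0.5:
                c, r = nodules_by_scan[sid][rng.integers(n_nod)]
                center = c + rng.normal(0, r / 2, size=3)
            else:
                center = rng.uniform(0, 100, size=3)
            dets.append((center, float(np.round(rng.random(), 3))))
        dets_by_scan[sid] = dets
    return dets_by_scan, nodules_by_scan, n_scans
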