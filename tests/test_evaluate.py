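import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from segcadx.cade import Candidate
from segcadx.evaluate import (
    bootstrap_ci,
    delong_test,
    froc,
    paired_fold_ttest,
    roc_auc,
    roc_pr_metrics,
    sensitivity_from_counts,
    stratified_sensitivity,
    stratify_by_size,
)
from tests.oracles import auc_pairwise, froc_exhaustive, random_detection_instance


def _to_candidates(dets_by_scan):
    return [
        Candidate(center_mm=c, radius_mm=1.0, score=s, series_id=sid)
        for sid, dets in dets_by_scan.items()
        for c, s in dets
    ]


# ---------------------------------------------------------------------
# printed-table arithmetic
# ---------------------------------------------------------------------

class TestSensitivityCounts:
    @pytest.mark.parametrize(
        "tp,fn,expected",
        [(457, 45, 91.0), (385, 18, 95.5), (278, 3, 98.9), (0, 5, 0.0)],
    )
    def test_percentage_to_one_decimal(self, tp, fn, expected):
        assert sensitivity_from_counts(tp, fn) == expected

    def test_undefined_for_empty_stratum(self):
        with pytest.raises(ValueError):
            sensitivity_from_counts(0, 0)


class TestStratification:
    def test_boundary_conventions(self):
        np.testing.assert_array_equal(
            stratify_by_size([6.0, 10.0, 10.1, 3.0, 25.0]), [1, 2, 3, 1, 3]
        )

    def test_strata_partition_the_nodule_set(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(3, 30, 200)
        s = stratify_by_size(d)
        assert np.bincount(s, minlength=4)[1:].sum() == 200
        with pytest.raises(ValueError):
            stratify_by_size([0.0])


# ---------------------------------------------------------------------
# FROC / CPM
# ---------------------------------------------------------------------

class TestFROC:
    def test_perfect_detector_scores_cpm_one(self):
        ann = {"a": [(np.zeros(3), 4.0)], "b": [(np.full(3, 50.0), 4.0)]}
        dets = [
            Candidate(np.zeros(3), 2, 1.0, "a"),
            Candidate(np.full(3, 50.0), 2, 1.0, "b"),
        ]
        res = froc(dets, ann, n_scans=2)
        assert res.cpm == 1.0
        assert res.sensitivities == [1.0] * 7
        assert np.all(np.diff(res.sensitivities) >= 0)

    def test_no_detections_scores_zero(self):
        ann = {"a": [(np.zeros(3), 4.0)]}
        assert froc([], ann, n_scans=1).cpm == 0.0
        with pytest.raises(ValueError):
            froc([], ann, n_scans=0)

    def test_crafted_two_scan_instance_matches_exhaustive_enumeration(self):
        nodules = {
            "s1": [(np.array([10.0, 10, 10]), 4.0), (np.array([30.0, 30, 30]), 4.0)],
            "s2": [(np.array([20.0, 20, 20]), 5.0)],
        }
        dets = {
            "s1": [
                (np.array([10.0, 10, 11]), 0.9),   # TP
                (np.array([70.0, 70, 70]), 0.8),   # FP
                (np.array([30.0, 30, 30]), 0.4),   # TP at low score
            ],
            "s2": [
                (np.array([20.0, 20, 21]), 0.7),   # TP
                (np.array([60.0, 10, 10]), 0.6),   # FP
            ],
        }
        res = froc(_to_candidates(dets), nodules, n_scans=2)
        sens_oracle, cpm_oracle = froc_exhaustive(dets, nodules, 2)
        assert res.sensitivities == pytest.approx(sens_oracle)
        assert res.cpm == pytest.approx(cpm_oracle)

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            dets, nodules, n_scans = random_detection_instance(rng)
            if sum(len(v) for v in nodules.values()) == 0:
                continue
            res = froc(_to_candidates(dets), nodules, n_scans)
            sens_oracle, cpm_oracle = froc_exhaustive(dets, nodules, n_scans)
            assert res.sensitivities == pytest.approx(sens_oracle), (dets, nodules)
            assert res.cpm == pytest.approx(cpm_oracle)
            assert res.cpm == pytest.approx(np.mean(res.sensitivities))
            checked += 1
        assert checked >= 150

    def test_stratified_sensitivity_counts_partition_the_nodules(self):
        rng = np.random.default_rng(3)
        rows = []
        dets = []
        for i in range(4):
            sid = f"s{i}"
            for j in range(3):
                center = rng.uniform(10, 80, 3)
                d = float(rng.uniform(3, 20))
                rows.append({"seriesuid": sid, "coordX": center[0],
                             "coordY": center[1], "coordZ": center[2],
                             "diameter_mm": d})
                if rng.random() < 0.8:
                    dets.append(Candidate(center + rng.normal(0, 0.5, 3),
                                          d / 2, float(rng.random()), sid))
        df = pd.DataFrame(rows)
        out = stratified_sensitivity(dets, df, n_scans=4)
        assert (out.tp + out.fn).sum() == len(df)


# ---------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        rep = roc_pr_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.roc_auc == 1.0 and rep.pr_auc == 1.0
        assert rep.youden_j == pytest.approx(1.0)

    def test_pairwise_example(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_matches_pairwise_enumeration_and_sklearn_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(2, size=n)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels)
            assert ours == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_independent_scores_give_auc_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.random(4000)
        labels = rng.integers(2, size=4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_auc_is_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        from scipy.special import expit

        assert roc_auc(expit(scores / 3.7), labels) == a
        assert roc_auc(np.exp(scores), labels) == a

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_metrics([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------
# DeLong and bootstrap
# ---------------------------------------------------------------------

class TestDeLong:
    def test_identical_scores_give_half(self):
        s = np.array([0.1, 0.9, 0.3, 0.7])
        y = np.array([0, 1, 0, 1])
        out = delong_test(s, s, y)
        assert out["p_value"] == 0.5 and out["degenerate"]

    def test_variance_agrees_with_bootstrap_on_synthetic_scores(self):
        rng = np.random.default_rng(10)
        n = 200
        labels = rng.integers(2, size=n)
        a = labels + rng.normal(0, 1.2, n)
        b = labels + rng.normal(0, 1.5, n)
        out = delong_test(a, b, labels)
        diffs = []
        for _ in range(600):
            idx = rng.integers(n, size=n)
            if labels[idx].min() == labels[idx].max():
                continue
            diffs.append(roc_auc(a[idx], labels[idx]) - roc_auc(b[idx], labels[idx]))
        assert out["var"] == pytest.approx(np.var(diffs), rel=0.25)

    def test_clearly_better_scores_get_small_p(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(2, size=300)
        good = labels + rng.normal(0, 0.5, 300)
        bad = rng.normal(0, 1, 300)
        assert delong_test(good, bad, labels)["p_value"] < 1e-4


class TestBootstrap:
    def _data(self, rng, n_patients=25, per=4):
        return pd.DataFrame(
            {
                "seriesuid": np.repeat([f"p{i}" for i in range(n_patients)], per),
                "value": rng.normal(1.0, 1.0, n_patients * per),
            }
        )

    def test_constant_metric_gives_zero_width_interval(self):
        data = self._data(np.random.default_rng(0))
        out = bootstrap_ci(lambda d: 3.14, data, n_boot=50, seed=0)
        assert out["lo95"] == out["hi95"] == 3.14

    def test_interval_contains_the_point_estimate(self):
        data = self._data(np.random.default_rng(1))
        out = bootstrap_ci(lambda d: d["value"].mean(), data, n_boot=300, seed=1)
        assert out["lo95"] <= out["point"] <= out["hi95"]

    def test_failing_resamples_are_redrawn_and_counted(self):
        data = self._data(np.random.default_rng(2), n_patients=6)
        calls = {"n": 0}

        def flaky(d):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("undefined on this resample")
            return d["value"].mean()

        out = bootstrap_ci(flaky, data, n_boot=40, seed=2)
        assert out["n_redrawn"] > 0

    def test_single_patient_rejected(self):
        df = pd.DataFrame({"seriesuid": ["a", "a"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, df, n_boot=10)


def test_paired_fold_ttest_detects_a_consistent_gap():
    a = np.array([0.90, 0.92, 0.91, 0.93, 0.90])
    b = a - np.array([0.030, 0.025, 0.035, 0.028, 0.032])
    out = paired_fold_ttest(a, b)
    assert out["p_value"] < 0.01 and out["t"] > 0
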