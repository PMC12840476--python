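import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segcadx import cade
from segcadx.cade import (
    Candidate,
    DetectionLossWeights,
    build_slab,
    detection_losses,
    extract_candidates,
    hard_negative_mining,
    match_detections,
    nms,
    smooth_l1,
    train_refine_head,
)
from segcadx.volume import Volume


def _cand(x, y, z, score, r=2.0):
    return Candidate(np.array([x, y, z], float), r, score)


# ---------------------------------------------------------------------
# candidate extraction / NMS
# ---------------------------------------------------------------------

class TestExtraction:
    def test_flat_zero_map_yields_no_candidates(self):
        assert extract_candidates(Volume(np.zeros((16, 16, 16)))) == []

    def test_single_gaussian_bump_yields_one_candidate_at_its_mode(self):
        g = np.mgrid[:24, :24, :24]
        d2 = sum((a - c) ** 2 for a, c in zip(g, (12, 10, 14)))
        prob = 0.9 * np.exp(-d2 / 18.0)
        cands = extract_candidates(Volume(prob), min_score=0.3)
        assert len(cands) == 1
        np.testing.assert_allclose(cands[0].center_mm, (12, 10, 14), atol=1.0)
        assert cands[0].score == pytest.approx(0.9, abs=1e-6)

    def test_two_close_bumps_are_merged_by_nms_keeping_the_stronger(self):
        g = np.mgrid[:24, :24, :24]
        d2a = sum((a - c) ** 2 for a, c in zip(g, (12, 12, 12)))
        d2b = sum((a - c) ** 2 for a, c in zip(g, (12, 12, 14)))  # 2 mm apart
        prob = np.maximum(0.9 * np.exp(-d2a / 8.0), 0.7 * np.exp(-d2b / 8.0))
        cands = extract_candidates(Volume(prob), min_score=0.3, nms_dist_mm=5.0)
        assert len(cands) == 1
        assert cands[0].score == pytest.approx(prob.max(), abs=1e-6)


class TestNMS:
    def test_degenerate_inputs(self):
        assert nms([], 5.0) == []
        one = [_cand(0, 0, 0, 0.5)]
        assert nms(one, 5.0) == one

    def test_three_collinear_candidates_keep_first_and_third(self):
        cands = [
            _cand(0, 0, 0, 0.9),
            _cand(3, 0, 0, 0.8),
            _cand(6, 0, 0, 0.7),
        ]
        kept = nms(cands, 5.0)
        assert [k.score for k in kept] == [0.9, 0.7]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.permutations(range(6)))
    def test_result_is_independent_of_input_order(self, perm):
        rng = np.random.default_rng(4)
        base = [
            _cand(*rng.uniform(0, 30, 3), score=round(s, 3))
            for s in rng.random(6)
        ]
        ref = {tuple(c.center_mm) for c in nms(base, 8.0)}
        out = {tuple(c.center_mm) for c in nms([base[i] for i in perm], 8.0)}
        assert out == ref


# ---------------------------------------------------------------------
# 2.5D slabs
# ---------------------------------------------------------------------

class TestSlabs:
    def _vol(self):
        rng = np.random.default_rng(0)
        return Volume(rng.random((40, 40, 40)) + 0.5)

    def test_central_candidate_needs_no_padding(self):
        slab = build_slab(self._vol(), _cand(20, 20, 20, 0.5), k_slices=5)
        assert slab.shape == (32, 32, 5)
        assert (slab > 0).all()

    def test_candidate_on_the_top_slice_pads_half_the_stack(self):
        slab = build_slab(self._vol(), _cand(20, 20, 0, 0.5), k_slices=5)
        assert not slab[:, :, :2].any()  # slices below the volume
        assert (slab[:, :, 2:] > 0).all()

    def test_shifting_by_one_voxel_in_z_shifts_the_slices(self):
        v = self._vol()
        a = build_slab(v, _cand(20, 20, 20, 0.5))
        b = build_slab(v, _cand(20, 20, 21, 0.5))
        np.testing.assert_array_equal(a[:, :, 1:], b[:, :, :-1])


# ---------------------------------------------------------------------
# detection losses
# ---------------------------------------------------------------------

class TestDetectionLosses:
    def test_confident_correct_class_has_zero_loss(self):
        out = detection_losses(
            np.array([0.0, 1.0]), np.zeros(4), 1, np.zeros(4)
        )
        assert out["L_cls"] == pytest.approx(0.0, abs=1e-9)
        assert out["L_det"] == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_costs_ln_two(self):
        out = detection_losses(np.array([0.5, 0.5]), np.zeros(4), 1, np.zeros(4))
        assert out["L_cls"] == pytest.approx(np.log(2), abs=1e-6)

    def test_smooth_l1_piecewise_values(self):
        assert smooth_l1(0.5) == pytest.approx(0.125)
        assert smooth_l1(2.0) == pytest.approx(1.5)
        assert smooth_l1(0.0) == pytest.approx(0.0)

    def test_joint_losses_combine_with_configured_weights(self):
        w = DetectionLossWeights(w_cls=2.0, w_loc=0.5, phi1=1.0, phi2=0.5)
        out = detection_losses(
            np.array([0.5, 0.5]), np.full(4, 0.5), 1, np.zeros(4),
            w=w, seg_loss_value=0.3,
        )
        assert out["L_loc"] == pytest.approx(0.125)
        assert out["L_det"] == pytest.approx(2 * np.log(2) + 0.5 * 0.125)
        assert out["L_cade"] == pytest.approx(0.3 + np.log(2) + 0.5 * 0.125)

    def test_losses_are_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet((1, 1))
            out = detection_losses(p, rng.normal(size=4), int(rng.integers(2)),
                                   rng.normal(size=4))
            assert min(out.values()) >= 0


# ---------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------

class TestMatching:
    def test_center_hit_is_tp_and_boundary_is_inclusive(self):
        nod = [(np.array([10.0, 10, 10]), 4.0)]
        res = match_detections([_cand(10, 10, 10, 0.9)], nod)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        res = match_detections([_cand(14, 10, 10, 0.9)], nod)  # exactly r
        assert res.tp == 1
        res = match_detections([_cand(14.01, 10, 10, 0.9)], nod)
        assert (res.tp, res.fp) == (0, 1)

    def test_duplicate_detections_of_a_hit_nodule_are_ignored(self):
        nod = [(np.array([10.0, 10, 10]), 4.0)]
        dets = [_cand(10, 10, 10, 0.9), _cand(11, 10, 10, 0.8)]
        res = match_detections(dets, nod)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.det_labels == ["TP", "IGN"]

    def test_highest_scoring_detection_claims_the_nodule(self):
        nod = [(np.array([10.0, 10, 10]), 4.0)]
        dets = [_cand(12, 10, 10, 0.3), _cand(10, 10, 10, 0.9)]
        res = match_detections(dets, nod)
        assert res.det_labels == ["IGN", "TP"]

    def test_counts_are_conserved_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            nodules = [
                (rng.uniform(0, 50, 3), float(rng.uniform(2, 6)))
                for _ in range(rng.integers(0, 4))
            ]
            dets = [
                _cand(*rng.uniform(0, 50, 3), score=float(rng.random()))
                for _ in range(rng.integers(0, 8))
            ]
            res = match_detections(dets, nodules)
            assert res.tp + res.fn == len(nodules)
            assert res.tp + res.fp + res.det_labels.count("IGN") == len(dets)


# ---------------------------------------------------------------------
# refinement head
# ---------------------------------------------------------------------

def _synthetic_slabs(rng, n, positive):
    """Bright 8 mm disc (nodule) vs. thin 2 mm line (vessel)."""
    out = []
    for _ in range(n):
        slab = rng.normal(0.1, 0.03, (32, 32, 5)).astype(np.float32)
        if positive:
            c = rng.integers(12, 20, size=2)
            g = np.mgrid[:32, :32]
            mask = (g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 <= 16
            slab[mask] += 0.6
        else:
            row = rng.integers(8, 24)
            slab[row : row + 2, :, :] += 0.6
        out.append(slab)
    return out


def test_refine_head_separates_nodules_from_vessel_like_negatives():
    rng = np.random.default_rng(0)
    train = [
        {"slab": s, "label": 1, "reg": np.array([4, 0, 0, 0], np.float32)}
        for s in _synthetic_slabs(rng, 24, True)
    ] + [{"slab": s, "label": 0} for s in _synthetic_slabs(rng, 24, False)]
    head = train_refine_head(train, seed=0, n_steps=300)
    pos = np.stack(_synthetic_slabs(rng, 10, True))
    neg = np.stack(_synthetic_slabs(rng, 10, False))
    p_pos, _ = cade.score_slabs(head, pos)
    p_neg, _ = cade.score_slabs(head, neg)
    from segcadx.evaluate import roc_auc

    scores = np.concatenate([p_pos, p_neg])
    labels = np.array([1] * 10 + [0] * 10)
    assert roc_auc(scores, labels) > 0.9


def test_refine_candidates_respects_offsets_and_threshold(monkeypatch):
    v = Volume(np.random.default_rng(0).random((40, 40, 40)))
    cands = [_cand(20, 20, 20, 0.5), _cand(10, 10, 10, 0.4)]

    def fake_score(model, slabs):
        return np.array([0.8, 0.3]), np.zeros((2, 4), np.float32)

    monkeypatch.setattr(cade, "score_slabs", fake_score)
    out = cade.refine_candidates(object(), cands, v, threshold=0.35)
    assert len(out) == 1  # second candidate dropped
    np.testing.assert_allclose(out[0].center_mm, (20, 20, 20))  # zero offsets
    assert out[0].score == pytest.approx(0.8)

    def all_low(model, slabs):
        return np.array([0.1, 0.1]), np.zeros((2, 4), np.float32)

    monkeypatch.setattr(cade, "score_slabs", all_low)
    assert cade.refine_candidates(object(), cands, v, threshold=1.0) == []


# ---------------------------------------------------------------------
# hard-negative mining
# ---------------------------------------------------------------------

class TestHardNegativeMining:
    def test_no_false_positives_leaves_the_pool_unchanged(self):
        pool = [{"slab": np.zeros((4, 4, 5)), "label": 1}]
        assert hard_negative_mining([], pool) == pool

    def test_mining_more_than_available_adds_each_fp_once(self):
        fps = [
            {"slab": np.full((2, 2, 1), i, float), "score": i / 10}
            for i in range(3)
        ]
        pool = []
        out = hard_negative_mining(fps, pool, n_mined=10)
        assert len(out) == 3
        assert all(e["label"] == 0 for e in out)
        # mining again with the same pool does not duplicate
        out2 = hard_negative_mining(fps, out, n_mined=10)
        assert len(out2) == 3

    def test_mining_suppresses_false_positive_scores(self):
        rng = np.random.default_rng(3)
        pool = [
            {"slab": s, "label": 1, "reg": np.array([4, 0, 0, 0], np.float32)}
            for s in _synthetic_slabs(rng, 10, True)
        ] + [{"slab": s, "label": 0} for s in _synthetic_slabs(rng, 4, False)]
        head = train_refine_head(pool, seed=1, n_steps=80)
        val_fps = np.stack(_synthetic_slabs(rng, 12, False))
        before, _ = cade.score_slabs(head, val_fps)
        mined = [
            {"slab": s, "score": float(p)}
            for s, p in zip(_synthetic_slabs(rng, 12, False),
                            rng.random(12))
        ]
        pool2 = hard_negative_mining(mined, pool, n_mined=12)
        head2 = train_refine_head(pool2, seed=1, n_steps=80)
        after, _ = cade.score_slabs(head2, val_fps)
        assert after.mean() <= before.mean() + 1e-6
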