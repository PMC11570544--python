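"""Detection / ReID heads: anchor assignment, loss kernels, attention,
NMS."""

import itertools

import numpy as np
import pytest

from cmttrack import jheads
from cmttrack.jheads import (ConvReID, Detection, FocalConfig, GroundTruthBox,
                             HeadConfig, JointHead, LossWeights, SAReID,
                             SpatialAttention, assign_positives, ciou,
                             ciou_loss, detection_loss, focal_loss, nms,
                             reid_loss, total_loss)
from cmttrack.nn import Tensor
from cmttrack.segnet import SegModel, extract_pyramid


# -------------------------------------------------------------- assignment
def test_anchor_positions_floor_division():
    boxes = [GroundTruthBox(100, 60, 10, 10, 0)]
    grid = assign_positives(boxes, 8, (12, 16))
    assert grid[7, 12] == 0 and (grid >= 0).sum() == 1
    grid = assign_positives([GroundTruthBox(7, 7, 4, 4, 0)], 8, (4, 4))
    assert grid[0, 0] == 0


def test_anchor_collision_keeps_larger_box():
    boxes = [GroundTruthBox(100, 60, 8, 8, 0), GroundTruthBox(101, 61, 12, 12, 1)]
    grid = assign_positives(boxes, 8, (10, 14))
    assert grid[7, 12] == 1
    with pytest.raises(ValueError):
        assign_positives([GroundTruthBox(500, 500, 5, 5, 0)], 8, (4, 4))


# ------------------------------------------------------------------- focal
def test_focal_loss_oracle_values():
    cfg = FocalConfig()
    # positive, p = 0.9: -0.25 * 0.1^2 * ln 0.9
    assert focal_loss(np.array([0.9]), np.array([True]), cfg) == pytest.approx(
        -0.25 * 0.01 * np.log(0.9), abs=1e-9)
    # negative, p = 0.9 -> p_t = 0.1
    assert focal_loss(np.array([0.9]), np.array([False]), cfg) == pytest.approx(
        -0.25 * 0.81 * np.log(0.1), abs=1e-6)
    assert focal_loss(np.array([0.9]), np.array([False]), cfg) == pytest.approx(
        0.4663, abs=1e-3)
    # perfectly confident -> ~0
    assert focal_loss(np.array([1.0 - 1e-7]), np.array([True]), cfg) < 1e-10


def test_focal_loss_tensor_matches_numeric(rng):
    cfg = FocalConfig()
    p = rng.uniform(0.05, 0.95, size=(5, 5))
    pos = rng.uniform(size=(5, 5)) > 0.7
    t = Tensor(p, requires_grad=True)
    val = focal_loss(t, pos, cfg)
    assert val.item() == pytest.approx(focal_loss(p, pos, cfg), abs=1e-9)
    val.backward()
    assert np.isfinite(t.grad).all()


# -------------------------------------------------------------------- CIOU
def _ciou_oracle(a, b):
    """Independent CIOU implementation (corner-based)."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    iou_v = inter / (a[2] * a[3] + b[2] * b[3] - inter)
    c2 = (max(ax2, bx2) - min(ax1, bx1)) ** 2 + (max(ay2, by2) - min(ay1, by1)) ** 2
    rho2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
    v = 4 / np.pi ** 2 * (np.arctan(a[2] / a[3]) - np.arctan(b[2] / b[3])) ** 2
    return iou_v - rho2 / c2 - (v / (1 - iou_v + v + 1e-12)) * v


def test_ciou_identical_and_oracle(rng):
    assert ciou_loss((5, 5, 10, 10), (5, 5, 10, 10)) == pytest.approx(0.0)
    assert ciou((0, 0, 10, 10), (5, 5, 10, 10)) == pytest.approx(
        _ciou_oracle((0, 0, 10, 10), (5, 5, 10, 10)), abs=1e-6)
    for _ in range(30):
        a = tuple(rng.uniform(5, 30, 2)) + tuple(rng.uniform(4, 20, 2))
        b = tuple(rng.uniform(5, 30, 2)) + tuple(rng.uniform(4, 20, 2))
        assert ciou(a, b) == pytest.approx(_ciou_oracle(a, b), abs=1e-6)
    with pytest.raises(ValueError):
        ciou_loss((0, 0, 0, 5), (0, 0, 5, 5))


# --------------------------------------------------------- detection total
def test_detection_loss_arithmetic():
    w = LossWeights()
    assert detection_loss([0.0], [0.0], w, n_pos=3) == 0.0
    # beta_c = 0 leaves only the normalized classification sum
    assert detection_loss([0.3, 0.2], [5.0], LossWeights(beta_c=0.0),
                          n_pos=2) == pytest.approx(0.25)
    # hand-built two-anchor case
    val = detection_loss([0.1, 0.4], [0.6, 0.2], w, n_pos=2)
    assert val == pytest.approx((0.1 + 0.4 + 0.05 * (0.6 + 0.2)) / 2)
    with pytest.raises(ValueError):
        detection_loss([0.1], [0.1], w, n_pos=0)


def test_total_loss_linear_in_eta():
    assert total_loss(1.0, 2.0, 0.05) == pytest.approx(1.1)
    assert total_loss(1.0, 2.0, 0.0) == 1.0
    vals = [total_loss(0.7, 1.3, e) for e in (0.0, 0.5, 1.0)]
    assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2)


# -------------------------------------------------------------------- ReID
def test_reid_printed_form_values():
    onehot = np.eye(4)[[0, 2, 1]]
    perfect = np.clip(onehot, 1e-12, 1.0)
    assert reid_loss(perfect, [0, 2, 1]) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((1, 4), 0.25)
    assert reid_loss(uniform, [2]) == pytest.approx(np.log(0.25))
    # N identical objects average to the single-object value
    rep = np.tile(uniform, (5, 1))
    assert reid_loss(rep, [2] * 5) == pytest.approx(reid_loss(uniform, [2]))
    with pytest.raises(ValueError):
        reid_loss(uniform, [7])


# --------------------------------------------------------------------- NMS
def _nms_oracle(dets, thr):
    """Brute force: the unique subset where every kept box is compatible
    with all higher-scoring kept boxes and every dropped box conflicts
    with some higher-scoring kept box."""
    best = None
    boxes = sorted(dets, key=lambda d: -d.score)
    for keep_mask in itertools.product([0, 1], repeat=len(boxes)):
        kept = [b for b, k in zip(boxes, keep_mask) if k]
        ok = True
        for i, b in enumerate(boxes):
            higher = [k for k in kept if k.score > b.score]
            conflict = any(jheads._iou(b.box, h.box) > thr for h in higher)
            if keep_mask[i] and conflict:
                ok = False
            if not keep_mask[i] and not conflict:
                ok = False
        if ok:
            best = kept
            break
    return best


def test_nms_examples_and_bruteforce(rng):
    a = Detection(10, 10, 8, 8, 0.9)
    b = Detection(10, 10, 8, 8, 0.8)
    out = nms([a, b], 0.5)
    assert len(out) == 1 and out[0].score == 0.9
    c = Detection(50, 50, 8, 8, 0.7)
    assert len(nms([a, c], 0.5)) == 2
    for _ in range(15):
        dets = [Detection(float(rng.uniform(0, 30)), float(rng.uniform(0, 30)),
                          float(rng.uniform(6, 14)), float(rng.uniform(6, 14)),
                          float(rng.uniform(0.1, 1.0)))
                for _ in range(6)]
        got = {d.score for d in nms(dets, 0.4)}
        want = {d.score for d in _nms_oracle(dets, 0.4)}
        assert got == want


# --------------------------------------------------------------- attention
def test_spatial_attention_contract(rng):
    sam = SpatialAttention(rng=np.random.default_rng(0))
    f = Tensor(rng.normal(size=(1, 6, 12, 12)))
    att = sam(f)
    assert att.shape == (1, 1, 12, 12)
    assert (att.data > 0).all() and (att.data < 1).all()
    const = Tensor(np.ones((1, 6, 12, 12)) * 0.3)
    amap = sam(const).data[0, 0]
    interior = amap[3:-3, 3:-3]
    assert np.allclose(interior, interior[0, 0])


def test_sa_reid_shapes_and_fuse_identity(trained_model):
    pyr = extract_pyramid(trained_model, np.zeros((256, 256)))
    channels = {r: t.shape[1] for r, t in pyr.maps.items()}
    reid = SAReID(channels, embed_dim=16, hidden=8, rng=np.random.default_rng(0))
    emb = reid(pyr)
    assert emb.shape == (1, 16, 32, 32)
    emb2 = reid(pyr)
    assert np.array_equal(emb.data, emb2.data)
    # f + f*0 = f: zero attention leaves features unchanged
    f = Tensor(np.random.default_rng(1).normal(size=(1, 8, 4, 4)))
    fused = f + f * Tensor(np.zeros((1, 1, 4, 4)))
    np.testing.assert_array_equal(fused.data, f.data)
    from cmttrack.segnet import FeaturePyramid
    with pytest.raises(ValueError):
        reid(FeaturePyramid({8: pyr.maps[8]}))


def test_joint_head_decode_and_loss_zero_state():
    """A head whose raw outputs exactly encode the GT reproduces the boxes
    at positive anchors with ~zero detection loss."""
    boxes = [GroundTruthBox(36, 28, 12, 14, 0)]
    r, anchor_scale = 8, 1.5
    a = anchor_scale * r
    hg = wg = 8
    raw = np.zeros((1, 5, hg, wg))
    raw[0, 4] = -20.0    # background everywhere
    ix, iy = int(36 // r), int(28 // r)
    # invert the decode: sigmoid(tx) = x/r - ix, exp(tw) = w / anchor
    raw[0, 0, iy, ix] = np.log((36 / r - ix) / (1 - (36 / r - ix)))
    raw[0, 1, iy, ix] = np.log((28 / r - iy) / (1 - (28 / r - iy)))
    raw[0, 2, iy, ix] = np.log(12 / a)
    raw[0, 3, iy, ix] = np.log(14 / a)
    raw[0, 4, iy, ix] = 20.0
    cfg = HeadConfig(embed_dim=8, hidden=4, anchor_scale=anchor_scale)
    head = JointHead({8: 5, 16: 5, 32: 5}, n_ids=2, cfg=cfg)
    dets = head.decode({8: Tensor(raw)})
    assert len(dets) == 1
    d = dets[0]
    assert (d.x, d.y) == pytest.approx((36, 28), abs=1e-6)
    assert (d.w, d.h) == pytest.approx((12, 14), abs=1e-6)
    assert ciou_loss(d.box, (36, 28, 12, 14)) == pytest.approx(0.0, abs=1e-9)
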