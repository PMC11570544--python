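"""Joint tracking heads on top of the segmentation feature pyramid.

An anchor-based detection branch (stacked 1x1 convolutions per resolution)
predicts a 5-vector t = (x*, y*, w*, h*, p) at every map location, trained
with a focal classification loss and a CIOU box-regression loss normalized
by the positive-anchor count.  The re-identification branch (SA-ReID)
upsamples the 1/16 and 1/32 pyramid levels to 1/8, encodes each with a 3x3
convolution, applies a spatial attention module (channel mean/max pooling,
7x7 convolution, sigmoid), fuses as f + f * attention, concatenates the
scales, and maps to ID embeddings with a final 3x3 convolution.  The joint
objective is L_det + eta * L_id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, Conv2d, ConvBNReLU, Module, Parameter, Tensor,
                 as_tensor, concat, maximum, minimum, upsample_to)
from .segnet import FeaturePyramid, SegModel, _to_batch

logger = logging.getLogger(__name__)

__all__ = [
    "FocalConfig", "LossWeights", "HeadConfig", "GroundTruthBox", "Detection",
    "assign_positives", "focal_loss", "ciou", "ciou_loss", "detection_loss",
    "reid_loss", "total_loss", "nms", "SpatialAttention", "SAReID", "ConvReID",
    "JointHead", "boxes_from_mask", "train_joint_head", "detect",
]

RESOLUTIONS = (8, 16, 32)


@dataclass(frozen=True)
class FocalConfig:
    alpha_c: float = 0.25
    gamma_c: float = 2.0
    # the printed focal form applies alpha_c to positives and negatives
    # alike; standard_alpha=True uses the conventional (alpha, 1-alpha) split
    standard_alpha: bool = False


@dataclass(frozen=True)
class LossWeights:
    beta_c: float = 0.05    # box-regression weight
    eta: float = 0.05       # ReID weight in the joint objective
    n_resolutions: int = 3


@dataclass
class HeadConfig:
    epochs: int = 30
    learning_rate: float = 3e-3
    embed_dim: int = 128
    hidden: int = 32
    anchor_scale: float = 1.5     # anchor side = anchor_scale * r
    score_threshold: float = 0.3
    nms_iou: float = 0.5
    # all three resolutions are supervised; inference decodes the finest
    # grid by default (a cell spans about one stride-8 anchor at desk scale,
    # and the coarse grids cannot localize it to better than their stride)
    decode_scales: tuple = (8,)
    use_sam: bool = True          # False: plain stacked-conv ReID (ablation)
    focal: FocalConfig = field(default_factory=FocalConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0


@dataclass(frozen=True)
class GroundTruthBox:
    """(x, y) box centre in pixels, (w, h) size, c the identity index."""

    x: float
    y: float
    w: float
    h: float
    c: int


@dataclass
class Detection:
    x: float
    y: float
    w: float
    h: float
    score: float
    r: int = 8
    embedding: np.ndarray | None = None

    @property
    def box(self):
        return (self.x, self.y, self.w, self.h)


# ------------------------------------------------------------- assignment
def assign_positives(boxes, r: int, grid_shape: tuple[int, int]):
    """Anchor grid labels for one resolution: location (floor(x/r),
    floor(y/r)) is positive for each ground-truth box; collisions keep the
    larger box (logged).  Returns an (Hg, Wg) int grid holding the index of
    the assigned box or -1."""
    hg, wg = grid_shape
    grid = np.full((hg, wg), -1, dtype=np.int64)
    areas = np.full((hg, wg), -1.0)
    for i, b in enumerate(boxes):
        ix, iy = int(b.x // r), int(b.y // r)
        if not (0 <= ix < wg and 0 <= iy < hg):
            raise ValueError(f"box centre ({b.x}, {b.y}) outside the grid")
        area = b.w * b.h
        if grid[iy, ix] != -1:
            logger.info("anchor collision at (%d,%d), r=%d", ix, iy, r)
            if area <= areas[iy, ix]:
                continue
        grid[iy, ix] = i
        areas[iy, ix] = area
    return grid


# ------------------------------------------------------------------ losses
def focal_loss(p, is_positive, cfg: FocalConfig = FocalConfig()):
    """Focal classification term -alpha_c (1-p_t)^gamma_c log(p_t) with
    p_t = p at positives and 1-p elsewhere.  Accepts floats/arrays (returns
    the summed value) or autodiff tensors (returns a scalar tensor)."""
    if isinstance(p, Tensor):
        pos = np.asarray(is_positive, dtype=bool)
        pc = p.clamp(1e-7, 1.0 - 1e-7)
        pt = pc * pos + (1.0 - pc) * (~pos)
        alpha = cfg.alpha_c if not cfg.standard_alpha else None
        if alpha is None:
            a = np.where(pos, cfg.alpha_c, 1.0 - cfg.alpha_c)
            return -((1.0 - pt) ** cfg.gamma_c * pt.log() * a).sum()
        return -((1.0 - pt) ** cfg.gamma_c * pt.log()).sum() * cfg.alpha_c
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    pos = np.asarray(is_positive, dtype=bool)
    pt = np.where(pos, p, 1.0 - p)
    a = cfg.alpha_c if not cfg.standard_alpha else np.where(
        pos, cfg.alpha_c, 1.0 - cfg.alpha_c)
    return float((-a * (1.0 - pt) ** cfg.gamma_c * np.log(pt)).sum())


def _corners(b):
    x, y, w, h = b
    return x - w * 0.5, y - h * 0.5, x + w * 0.5, y + h * 0.5


def ciou(box_a, box_b) -> float:
    """Complete-IoU of two centre-format boxes (numeric form)."""
    ax1, ay1, ax2, ay2 = _corners(box_a)
    bx1, by1, bx2, by2 = _corners(box_b)
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = box_a[2] * box_a[3] + box_b[2] * box_b[3] - inter
    iou = inter / union
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch
    rho2 = (box_a[0] - box_b[0]) ** 2 + (box_a[1] - box_b[1]) ** 2
    v = 4.0 / np.pi ** 2 * (np.arctan(box_a[2] / box_a[3])
                            - np.arctan(box_b[2] / box_b[3])) ** 2
    alpha = v / (1.0 - iou + v + 1e-12)
    return float(iou - rho2 / c2 - alpha * v)


def ciou_loss(pred_box, gt_box) -> float:
    """1 - CIOU for a positive anchor (numeric form)."""
    if pred_box[2] <= 0 or pred_box[3] <= 0:
        raise ValueError("degenerate predicted box")
    return 1.0 - ciou(pred_box, gt_box)


def _ciou_loss_t(px, py, pw, ph, gt: GroundTruthBox) -> Tensor:
    """Differentiable 1 - CIOU of a predicted box (tensor components)
    against a fixed ground-truth box; the trade-off coefficient alpha is
    treated as a constant, as is standard."""
    ax1, ay1 = px - pw * 0.5, py - ph * 0.5
    ax2, ay2 = px + pw * 0.5, py + ph * 0.5
    bx1, by1, bx2, by2 = _corners((gt.x, gt.y, gt.w, gt.h))
    zero = Tensor(0.0)
    iw = maximum(zero, minimum(ax2, bx2) - maximum(ax1, bx1))
    ih = maximum(zero, minimum(ay2, by2) - maximum(ay1, by1))
    inter = iw * ih
    union = pw * ph + gt.w * gt.h - inter
    iou = inter / union
    cw = maximum(ax2, bx2) - minimum(ax1, bx1)
    ch = maximum(ay2, by2) - minimum(ay1, by1)
    c2 = cw * cw + ch * ch
    rho2 = (px - gt.x) ** 2 + (py - gt.y) ** 2
    v = (4.0 / np.pi ** 2) * ((pw / ph).arctan() - np.arctan(gt.w / gt.h)) ** 2
    alpha_const = float(v.data / (1.0 - iou.data + v.data + 1e-12))
    return 1.0 - iou + rho2 / c2 + alpha_const * v


def detection_loss(cls_terms, reg_terms, weights: LossWeights, n_pos: int):
    """(1/N_pos) * sum over resolutions and locations of
    (L_cls + beta_c * L_reg)."""
    if n_pos < 1:
        raise ValueError("no positive samples; image should be skipped")
    total = sum(cls_terms) + weights.beta_c * sum(reg_terms)
    return total * (1.0 / n_pos) if isinstance(total, Tensor) \
        else float(total / n_pos)


def reid_loss(class_probs, labels) -> float:
    """Eq-as-printed ReID quantity (1/N) sum_i sum_c Y^i(c) log p_i(c); the
    conventional optimization objective is its negative (see
    ``reid_nll``)."""
    p = np.asarray(class_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if (labels < 0).any() or (labels >= p.shape[1]).any():
        raise ValueError("label outside [1..C]")
    n = p.shape[0]
    return float(np.log(np.clip(p[np.arange(n), labels], 1e-12, 1.0)).sum() / n)


def reid_nll(log_probs: Tensor, labels) -> Tensor:
    """Negative cross-entropy form used for optimization."""
    labels = np.asarray(labels, dtype=np.int64)
    n = log_probs.shape[0]
    picked = log_probs[(np.arange(n), labels)]
    return -(picked.mean())


def total_loss(det, rid, eta: float = 0.05):
    """Joint objective L_det + eta * L_id."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return det + eta * rid


def _iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = _corners(a)
    bx1, by1, bx2, by2 = _corners(b)
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def nms(detections: list[Detection], iou_threshold: float = 0.5):
    """Greedy non-maximum suppression by descending score."""
    order = sorted(detections, key=lambda d: -d.score)
    keep: list[Detection] = []
    for d in order:
        if all(_iou(d.box, k.box) <= iou_threshold for k in keep):
            keep.append(d)
    return keep


# ----------------------------------------------------------------- modules
class SpatialAttention(Module):
    """Channel mean + max pooling -> 7x7 conv -> sigmoid attention map."""

    def __init__(self, *, rng):
        super().__init__()
        self.conv = Conv2d(2, 1, 7, padding=3, rng=rng)

    def __call__(self, f: Tensor) -> Tensor:
        pooled = concat([f.mean(axis=1, keepdims=True),
                         f.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()


class SAReID(Module):
    """Spatial-attention ReID: per scale upsample to 1/8, 3x3 conv encode,
    SAM, fuse f + f*attention, concat scales, 3x3 conv to embeddings."""

    def __init__(self, channels: dict, embed_dim: int = 128, hidden: int = 32,
                 *, rng):
        super().__init__()
        self.enc8 = ConvBNReLU(channels[8], hidden, rng=rng)
        self.enc16 = ConvBNReLU(channels[16], hidden, rng=rng)
        self.enc32 = ConvBNReLU(channels[32], hidden, rng=rng)
        self.sam8 = SpatialAttention(rng=rng)
        self.sam16 = SpatialAttention(rng=rng)
        self.sam32 = SpatialAttention(rng=rng)
        self.out = Conv2d(3 * hidden, embed_dim, 3, padding=1, rng=rng)
        self.embed_dim = embed_dim

    def __call__(self, pyramid: FeaturePyramid) -> Tensor:
        for r in RESOLUTIONS:
            if r not in pyramid.maps:
                raise ValueError(f"pyramid is missing the 1/{r} scale")
        size8 = pyramid.maps[8].shape[2:]
        fused = []
        for r, enc, sam in ((8, self.enc8, self.sam8),
                            (16, self.enc16, self.sam16),
                            (32, self.enc32, self.sam32)):
            f = enc(upsample_to(as_tensor(pyramid.maps[r]), size8)
                    if r != 8 else as_tensor(pyramid.maps[r]))
            fused.append(f + f * sam(f))
        return self.out(concat(fused, axis=1))


class ConvReID(Module):
    """Ablation ReID branch: same layout but plain stacked convolutions,
    no spatial attention."""

    def __init__(self, channels: dict, embed_dim: int = 128, hidden: int = 32,
                 *, rng):
        super().__init__()
        self.enc8 = ConvBNReLU(channels[8], hidden, rng=rng)
        self.enc16 = ConvBNReLU(channels[16], hidden, rng=rng)
        self.enc32 = ConvBNReLU(channels[32], hidden, rng=rng)
        self.out = Conv2d(3 * hidden, embed_dim, 3, padding=1, rng=rng)
        self.embed_dim = embed_dim

    def __call__(self, pyramid: FeaturePyramid) -> Tensor:
        size8 = pyramid.maps[8].shape[2:]
        feats = []
        for r, enc in ((8, self.enc8), (16, self.enc16), (32, self.enc32)):
            f = enc(upsample_to(as_tensor(pyramid.maps[r]), size8)
                    if r != 8 else as_tensor(pyramid.maps[r]))
            feats.append(f)
        return self.out(concat(feats, axis=1))


class _DetBranch(Module):
    """Stacked 1x1 convolutions -> 5 channels (tx, ty, tw, th, logit p)."""

    def __init__(self, cin: int, hidden: int, *, rng):
        super().__init__()
        self.c1 = Conv2d(cin, hidden, 1, rng=rng)
        self.c2 = Conv2d(hidden, 5, 1, rng=rng)

    def __call__(self, f: Tensor) -> Tensor:
        return self.c2(self.c1(f).relu())


class JointHead(Module):
    """Detection branches at 1/8, 1/16, 1/32 plus the ReID branch and the
    training-time identity classifier."""

    def __init__(self, channels: dict, n_ids: int, cfg: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.det8 = _DetBranch(channels[8], cfg.hidden, rng=rng)
        self.det16 = _DetBranch(channels[16], cfg.hidden, rng=rng)
        self.det32 = _DetBranch(channels[32], cfg.hidden, rng=rng)
        for br in (self.det8, self.det16, self.det32):
            br.c2.bias.data[4] = -3.0   # low-foreground prior (focal init)
        reid_cls = SAReID if cfg.use_sam else ConvReID
        self.reid = reid_cls(channels, cfg.embed_dim, cfg.hidden, rng=rng)
        self.n_ids = n_ids
        scale = 1.0 / np.sqrt(cfg.embed_dim)
        self.cls_w = Parameter(rng.normal(0, scale, (cfg.embed_dim, n_ids)))
        self.cls_b = Parameter(np.zeros(n_ids))

    def det_raw(self, pyramid: FeaturePyramid) -> dict:
        return {8: self.det8(as_tensor(pyramid.maps[8])),
                16: self.det16(as_tensor(pyramid.maps[16])),
                32: self.det32(as_tensor(pyramid.maps[32]))}

    def decode(self, raw: dict) -> list[Detection]:
        """YOLO-style decode, one anchor per location."""
        dets = []
        for r, t in raw.items():
            if r not in self.cfg.decode_scales:
                continue
            a = self.cfg.anchor_scale * r
            data = t.data[0]
            hg, wg = data.shape[1:]
            p = 1.0 / (1.0 + np.exp(-data[4]))
            sx = 1.0 / (1.0 + np.exp(-data[0]))
            sy = 1.0 / (1.0 + np.exp(-data[1]))
            gx, gy = np.meshgrid(np.arange(wg), np.arange(hg))
            xs = (gx + sx) * r
            ys = (gy + sy) * r
            ws = a * np.exp(np.clip(data[2], -4, 4))
            hs = a * np.exp(np.clip(data[3], -4, 4))
            for iy, ix in zip(*np.nonzero(p >= self.cfg.score_threshold)):
                dets.append(Detection(float(xs[iy, ix]), float(ys[iy, ix]),
                                      float(ws[iy, ix]), float(hs[iy, ix]),
                                      float(p[iy, ix]), r))
        return dets


# ----------------------------------------------------------- training utils
def boxes_from_mask(mask: np.ndarray, id_map: dict) -> list[GroundTruthBox]:
    """Ground-truth boxes from an instance mask; identity index via the
    track-label -> class map."""
    boxes = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        ys, xs = np.nonzero(mask == lab)
        w = xs.max() - xs.min() + 1.0
        h = ys.max() - ys.min() + 1.0
        boxes.append(GroundTruthBox(float(xs.mean()), float(ys.mean()),
                                    float(w), float(h), id_map[int(lab)]))
    return boxes


def _frame_loss(head: JointHead, pyramid: FeaturePyramid,
                boxes: list[GroundTruthBox]):
    cfg = head.cfg
    raw = head.det_raw(pyramid)
    cls_terms, reg_terms = [], []
    n_pos = 0
    for r, t in raw.items():
        hg, wg = t.shape[2:]
        grid = assign_positives(boxes, r, (hg, wg))
        pos = grid >= 0
        n_pos += int(pos.sum())
        p = t[(0, 4)].sigmoid()
        cls_terms.append(focal_loss(p, pos, cfg.focal))
        a = cfg.anchor_scale * r
        for iy, ix in zip(*np.nonzero(pos)):
            b = boxes[grid[iy, ix]]
            px = (Tensor(float(ix)) + t[(0, 0, int(iy), int(ix))].sigmoid()) * r
            py = (Tensor(float(iy)) + t[(0, 1, int(iy), int(ix))].sigmoid()) * r
            pw = t[(0, 2, int(iy), int(ix))].clamp(-4, 4).exp() * a
            ph = t[(0, 3, int(iy), int(ix))].clamp(-4, 4).exp() * a
            reg_terms.append(_ciou_loss_t(px, py, pw, ph, b))
    if n_pos == 0:
        return None
    det = detection_loss(cls_terms, reg_terms, cfg.weights, n_pos)
    # ReID: embeddings at 1/8 positive anchors -> identity classifier
    emb_map = head.reid(pyramid)
    grid8 = assign_positives(boxes, 8, tuple(emb_map.shape[2:]))
    iys, ixs = np.nonzero(grid8 >= 0)
    labels = [boxes[grid8[iy, ix]].c for iy, ix in zip(iys, ixs)]
    emb = emb_map[(0, slice(None), iys, ixs)]   # (N, D): advanced dims first
    logits = emb @ head.cls_w + head.cls_b
    rid = reid_nll(logits.log_softmax(axis=-1), labels)
    return total_loss(det, rid, cfg.weights.eta)


def train_joint_head(model: SegModel, frames, masks, cfg: HeadConfig,
                     id_map: dict | None = None):
    """Train the joint head on labelled frames, backbone frozen.

    ``masks`` are instance masks whose labels are stable identities across
    frames; the pyramid features come from the (adapted) segmentation unit
    and are treated as fixed inputs.
    """
    if id_map is None:
        labels = sorted({int(l) for mk in masks for l in np.unique(mk) if l})
        id_map = {lab: i for i, lab in enumerate(labels)}
    model.eval()
    pyramids = []
    for img in frames:
        _, pyr = model(Tensor(_to_batch(img)), return_pyramid=True)
        pyramids.append(FeaturePyramid(
            {r: Tensor(t.data) for r, t in pyr.maps.items()}))  # detached
    channels = {r: t.shape[1] for r, t in pyramids[0].maps.items()}
    head = JointHead(channels, n_ids=len(id_map), cfg=cfg)
    gt = [boxes_from_mask(np.asarray(mk), id_map) for mk in masks]
    opt = Adam(head.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(pyramids))
        losses = []
        for i in order:
            loss = _frame_loss(head, pyramids[i], gt[i])
            if loss is None:
                logger.info("frame %d has no positive anchors; skipped", i)
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return head, id_map, history


def detect(model: SegModel, head: JointHead, image) -> list[Detection]:
    """Detections with ID embeddings for one frame: decode all scales,
    score-threshold, NMS, then attach the 1/8-scale embedding at each
    detection centre."""
    model.eval()
    head.eval()
    _, pyr = model(Tensor(_to_batch(image)), return_pyramid=True)
    dets = nms(head.decode(head.det_raw(pyr)), head.cfg.nms_iou)
    emb_map = head.reid(pyr).data[0]
    h8, w8 = emb_map.shape[1:]
    for d in dets:
        ix = min(int(d.x // 8), w8 - 1)
        iy = min(int(d.y // 8), h8 - 1)
        v = emb_map[:, iy, ix]
        d.embedding = v / (np.linalg.norm(v) + 1e-12)
    return dets
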