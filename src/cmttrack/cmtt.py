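"""Central-metric two-stage fully test-time adaptation (CMTT).

Stage 1 adapts on entire target images with a Shannon-entropy +
batch-nuclear-norm objective; Stage 2 adapts on overlapping patches with a
central-metric contrastive (CMC) loss whose center delta is a statistic of
the background pixels predicted in Stage 1.  Only batch-normalization
affine parameters (gamma, beta) are optimized; BN normalization statistics
are re-estimated from target batches; every other weight stays frozen.
The two stage predictions are combined by a weighted average.

The CMC loss is exposed in two forms.  ``cmc_loss`` is the printed hard-set
form: with fixed pixel partitions it is the quantity the ablation tables
report, but it is constant with respect to the model parameters.  For
gradient-based adaptation ``cmc_loss_soft`` replaces the hard membership of
each pixel with the model's current foreground probability, which recovers
the printed value when the probabilities are binary and provides the
gradient path through the network.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm2d, Tensor, as_tensor
from .segnet import SegModel, _to_batch, predict_mask

logger = logging.getLogger(__name__)

__all__ = [
    "AdaptationConfig", "Center", "PatchGrid", "AdaptationResult",
    "EmptyForegroundError", "AllPatchesSkippedError",
    "shannon_entropy_loss", "bnm_loss", "entire_image_loss", "similarity",
    "compute_center", "cmc_loss", "cmc_loss_soft", "split_patches",
    "stitch_patches", "adaptable_parameters", "recalibrate_bn",
    "adapt_stage1", "adapt_stage2", "aggregate_predictions", "adapt",
    "two_class_responses",
]


class EmptyForegroundError(ValueError):
    """CMC loss is undefined when the predicted cell set is empty."""


class AllPatchesSkippedError(RuntimeError):
    """Stage 2 cannot run if every patch lacks predicted foreground."""


@dataclass
class AdaptationConfig:
    alpha: float = 0.5                 # weight of the BNM term
    stage1_epochs: int = 3
    stage2_epochs: int = 3             # <10 epochs total by default
    learning_rate: float = 1e-4
    batch_size: int = 4
    patch_size: int = 128
    patch_overlap: int = 32
    delta_mode: str = "median"         # or "mean"
    aggregation_weight: float = 0.5    # w on the Stage-1 prediction
    cmc_orientation: str = "printed"   # or "flipped" (swaps P+/P- roles)
    stage2_loss: str = "cmc"           # or "shannon" (ablation)
    threshold: float = 0.5             # binarization of probability maps
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.aggregation_weight <= 1.0:
            raise ValueError("aggregation_weight must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.delta_mode not in ("median", "mean"):
            raise ValueError("delta_mode must be 'median' or 'mean'")


@dataclass
class Center:
    """Background-center statistic delta of one patch."""

    delta: float
    mode: str
    fallback_used: bool = False


@dataclass
class PatchGrid:
    """Tiling of a frame into (possibly overlapping) patches with per-patch
    stitch weights that form a partition of unity after normalization."""

    patches: list          # (row0, col0, h, w)
    weights: list          # per-patch (h, w) stitch weight arrays
    frame_shape: tuple


# ----------------------------------------------------------------- losses
def two_class_responses(prob):
    """Turn a foreground-probability map into explicit two-column
    (cell, background) responses with rows summing to one."""
    if isinstance(prob, Tensor):
        flat = prob.reshape(-1, 1)
        from .nn import concat
        return concat([flat, 1.0 - flat], axis=1)
    p = np.asarray(prob, dtype=np.float64).reshape(-1, 1)
    return np.concatenate([p, 1.0 - p], axis=1)


def shannon_entropy_loss(probs, eps: float = 1e-12):
    """Mean per-pixel Shannon entropy -sum_c p_c ln p_c (natural log)."""
    if isinstance(probs, Tensor):
        p = probs.clamp(eps, 1.0)
        ent = -(probs * p.log()).sum(axis=-1)
        return ent.mean()
    p = np.asarray(probs, dtype=np.float64)
    if (p < -1e-12).any():
        raise ValueError("probabilities must be non-negative")
    q = np.clip(p, eps, 1.0)
    return float((-(p * np.log(q)).sum(axis=-1)).mean())


def bnm_loss(responses):
    """Negative mean nuclear norm of the batch response matrix:
    -(1/B) * ||A||_*  with B the number of rows."""
    if isinstance(responses, Tensor):
        b = responses.shape[0]
        return responses.nuclear_norm() * (-1.0 / b)
    a = np.asarray(responses, dtype=np.float64)
    if not np.isfinite(a).all():
        raise ValueError("responses must be finite")
    return float(-np.linalg.svd(a, compute_uv=False).sum() / a.shape[0])


def entire_image_loss(probs, responses, alpha: float):
    """Stage-1 objective  L_E = L_s + alpha * L_bnm."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return shannon_entropy_loss(probs) + alpha * bnm_loss(responses)


def similarity(i, j):
    """Normalized inverse Euclidean distance phi(i, j) = 1/(1 + ||i-j||^2),
    in (0, 1]; operands are pixel values in [0, 1] (scalars or vectors)."""
    d = np.asarray(i, dtype=np.float64) - np.asarray(j, dtype=np.float64)
    if d.ndim == 0:
        return float(1.0 / (1.0 + d * d))
    return 1.0 / (1.0 + (d * d if d.ndim == 1 else (d ** 2).sum(axis=-1)))


def compute_center(patch, stage1_mask, mode: str = "median",
                   fallback: float | None = None) -> Center:
    """delta = median (or mean) of patch pixels predicted background in
    Stage 1.  With no background pixels, falls back to a global frame
    statistic (flagged and logged)."""
    patch = np.asarray(patch, dtype=np.float64)
    bg = patch[~np.asarray(stage1_mask, dtype=bool)]
    stat = np.median if mode == "median" else np.mean
    if bg.size == 0:
        if fallback is None:
            raise EmptyForegroundError(
                "no background pixels in patch and no global fallback given")
        logger.warning("patch has no predicted background; "
                       "using global background statistic %.4f", fallback)
        return Center(float(fallback), mode, fallback_used=True)
    return Center(float(stat(bg)), mode)


def cmc_loss(patch_pixels, p_plus, p_minus, delta: float) -> float:
    """Central-metric contrastive loss, hard-set form exactly as printed:

        L = -log( S+ / (S+ + S-) ),   S± = sum_{i in P±} exp(phi(i, delta))

    P+ (cell) and P- (background) are disjoint index sets from the
    binarized Stage-1 prediction.  Empty P+ makes the loss undefined.
    """
    px = np.asarray(patch_pixels, dtype=np.float64).ravel()
    p_plus = np.asarray(p_plus)
    p_minus = np.asarray(p_minus)
    if p_plus.dtype == bool:
        p_plus = np.flatnonzero(p_plus.ravel())
        p_minus = np.flatnonzero(p_minus.ravel())
    if p_plus.size == 0:
        raise EmptyForegroundError("P+ is empty: CMC loss undefined")
    phi = similarity(px, delta)
    s_plus = np.exp(phi[p_plus]).sum()
    s_minus = np.exp(phi[p_minus]).sum() if p_minus.size else 0.0
    return float(-np.log(s_plus / (s_plus + s_minus)))


def cmc_loss_soft(fg_prob: Tensor, phi: np.ndarray,
                  orientation: str = "printed") -> Tensor:
    """Soft-membership CMC: S+ = sum_i q_i e^{phi_i}, S- = sum_i (1-q_i)
    e^{phi_i} with q the current foreground probability; reduces to the
    printed form for binary q.  ``orientation='flipped'`` swaps the roles
    of P+ and P- (the intuitive reading of the objective)."""
    w = Tensor(np.exp(phi))
    q = fg_prob if orientation == "printed" else (1.0 - fg_prob)
    s_num = (q * w).sum()
    total = float(np.exp(phi).sum())
    return -( (s_num * (1.0 / total)).clamp(1e-12, 1.0).log() )


# ------------------------------------------------------------------ patches
def _ramp(n: int, overlap: int) -> np.ndarray:
    w = np.ones(n)
    L = min(overlap, n)
    if L > 0:
        t = (np.arange(L) + 0.5) / L
        edge = 0.5 - 0.5 * np.cos(np.pi * t)   # cosine ramp 0 -> 1
        w[:L] = np.maximum(edge, 1e-3)
        w[-L:] = np.minimum(w[-L:], np.maximum(edge[::-1], 1e-3))
    return w


def _starts(size: int, patch: int, step: int) -> list[int]:
    s = list(range(0, max(size - patch, 0) + 1, step))
    if s[-1] + patch < size:
        s.append(size - patch)
    return s


def split_patches(image, patch_size: int, overlap: int) -> PatchGrid:
    """Tile a frame into overlapping patches covering every pixel."""
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    if overlap >= patch_size:
        raise ValueError("overlap must be smaller than patch_size")
    img = np.asarray(image)
    h, w = img.shape[-2:]
    ph, pw = min(patch_size, h), min(patch_size, w)
    step_r = max(ph - overlap, 1)
    step_c = max(pw - overlap, 1)
    patches, weights = [], []
    wr = _ramp(ph, overlap)
    wc = _ramp(pw, overlap)
    wpatch = np.outer(wr, wc)
    for r0 in _starts(h, ph, step_r):
        for c0 in _starts(w, pw, step_c):
            patches.append((r0, c0, ph, pw))
            weights.append(wpatch)
    return PatchGrid(patches, weights, (h, w))


def stitch_patches(grid: PatchGrid, patch_preds) -> np.ndarray:
    """Stitch per-patch predictions into a frame-sized map by the
    normalized stitch-weighted average.  Stitching crops of one map
    reproduces that map exactly (partition of unity)."""
    acc = np.zeros(grid.frame_shape)
    tot = np.zeros(grid.frame_shape)
    for (r0, c0, h, w), wgt, pred in zip(grid.patches, grid.weights, patch_preds):
        acc[r0:r0 + h, c0:c0 + w] += wgt * np.asarray(pred)
        tot[r0:r0 + h, c0:c0 + w] += wgt
    return acc / tot


# --------------------------------------------------------------- adaptation
def adaptable_parameters(model: SegModel):
    """Exactly the BN affine parameters (gamma, beta); everything else is
    frozen during test-time adaptation."""
    params = model.bn_parameters()
    if not params:
        raise ValueError("model has no batch-normalization layers")
    return params


def recalibrate_bn(model: SegModel, images: np.ndarray) -> None:
    """Re-estimate every BN layer's normalization statistics from a target
    batch (one forward pass with full-replacement momentum)."""
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    model.train()
    model(Tensor(images))
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.eval()


def adapt_stage1(model: SegModel, target_images, cfg: AdaptationConfig):
    """Entire-image adaptation: minimize L_E = entropy + alpha * BNM over
    target batches, updating only BN affine parameters.  Returns the model
    and its Stage-1 predictions, plus a per-epoch loss log."""
    x = _to_batch(target_images)
    if x.shape[0] == 0:
        raise ValueError("empty target set")
    log = {"stage": 1, "epoch_losses": []}
    if cfg.stage1_epochs > 0:
        recalibrate_bn(model, x)
        opt = Adam(adaptable_parameters(model), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        model.train()
        for _ in range(cfg.stage1_epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            for s in range(0, x.shape[0], cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                prob = model(Tensor(x[idx]))
                responses = two_class_responses(prob)
                loss = entire_image_loss(responses, responses, cfg.alpha)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            log["epoch_losses"].append(float(np.mean(losses)))
        model.eval()
    pred1 = [predict_mask(model, img) for img in np.asarray(target_images)]
    return model, pred1, log


def adapt_stage2(model: SegModel, target_images, pred1, cfg: AdaptationConfig):
    """Patch adaptation with the (soft) CMC loss; delta per patch comes from
    the fixed Stage-1 prediction; only BN affine parameters move."""
    imgs = [np.asarray(im, dtype=np.float64) for im in np.asarray(target_images)]
    from .segnet import MIN_IMAGE_SIZE
    patch_size = max(cfg.patch_size, MIN_IMAGE_SIZE)  # encoder depth floor
    overlap = min(cfg.patch_overlap, patch_size - 1)
    grids = [split_patches(im, patch_size, overlap) for im in imgs]
    patch_x, patch_phi, skipped = [], [], 0
    for im, p1, grid in zip(imgs, pred1, grids):
        fg_global = np.asarray(p1) >= cfg.threshold
        global_bg = im[~fg_global]
        stat = np.median if cfg.delta_mode == "median" else np.mean
        fallback = float(stat(global_bg)) if global_bg.size else float(np.median(im))
        for (r0, c0, h, w) in grid.patches:
            px = im[r0:r0 + h, c0:c0 + w]
            fg = fg_global[r0:r0 + h, c0:c0 + w]
            if not fg.any():
                skipped += 1
                logger.info("patch at (%d,%d) has no Stage-1 foreground; skipped",
                            r0, c0)
                continue
            center = compute_center(px, fg, cfg.delta_mode, fallback=fallback)
            patch_x.append(px)
            patch_phi.append(similarity(px.ravel(), center.delta)
                             .reshape(px.shape))
    if not patch_x:
        raise AllPatchesSkippedError(
            "no patch contains predicted foreground; Stage 2 cannot adapt")
    log = {"stage": 2, "epoch_losses": [], "patches_skipped": skipped}
    if cfg.stage2_epochs > 0:
        px_arr = np.stack(patch_x)[:, None]         # (P, 1, h, w)
        recalibrate_bn(model, px_arr)
        opt = Adam(adaptable_parameters(model), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        model.train()
        for _ in range(cfg.stage2_epochs):
            order = rng.permutation(len(patch_x))
            losses = []
            for s in range(0, len(patch_x), cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                prob = model(Tensor(px_arr[idx]))
                if cfg.stage2_loss == "shannon":
                    loss = shannon_entropy_loss(two_class_responses(prob))
                else:
                    loss_terms = [
                        cmc_loss_soft(prob[int(pos), 0], patch_phi[int(k)],
                                      cfg.cmc_orientation)
                        for pos, k in enumerate(idx)]
                    loss = loss_terms[0]
                    for t in loss_terms[1:]:
                        loss = loss + t
                    loss = loss * (1.0 / len(loss_terms))
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            log["epoch_losses"].append(float(np.mean(losses)))
        model.eval()
    # prediction 2: per-patch prediction stitched back to frame size
    pred2 = []
    for im, grid in zip(imgs, grids):
        preds = [predict_mask(model, im[r0:r0 + h, c0:c0 + w])
                 for (r0, c0, h, w) in grid.patches]
        pred2.append(stitch_patches(grid, preds))
    return model, pred2, log


def aggregate_predictions(pred1, pred2, w: float) -> np.ndarray:
    """Weighted average w * pred1 + (1 - w) * pred2 of the two stage
    probability maps."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    p1 = np.asarray(pred1, dtype=np.float64)
    p2 = np.asarray(pred2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValueError("prediction shapes differ")
    return w * p1 + (1.0 - w) * p2


@dataclass
class AdaptationResult:
    model: SegModel
    pred1: list
    pred2: list
    final: list
    masks: list
    logs: list = field(default_factory=list)


def adapt(model: SegModel, target_images, cfg: AdaptationConfig | None = None,
          use_stage2: bool = True) -> AdaptationResult:
    """Run the full two-stage adaptation and aggregate the predictions."""
    cfg = cfg or AdaptationConfig()
    model, pred1, log1 = adapt_stage1(model, target_images, cfg)
    logs = [log1]
    if use_stage2:
        model, pred2, log2 = adapt_stage2(model, target_images, pred1, cfg)
        logs.append(log2)
        final = [aggregate_predictions(a, b, cfg.aggregation_weight)
                 for a, b in zip(pred1, pred2)]
    else:
        pred2 = pred1
        final = pred1
    masks = [(f >= cfg.threshold).astype(np.uint8) for f in final]
    return AdaptationResult(model, pred1, pred2, final, masks, logs)
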