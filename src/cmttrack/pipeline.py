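"""End-to-end experiment harness: generate synthetic source/target domains,
train the segmentation unit, run CMTT test-time adaptation, train the joint
detection + ReID head, track the target video, and evaluate the full metric
suite.  Every run is a pure function of (config, seed).

The default scene configurations are the package's study conditions: a
sparse, high-contrast source domain; a photometrically shifted target with
three times the cell density for segmentation adaptation; and an easy,
well-separated low-noise video for tracking.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import metrics
from .assoc import AssociationConfig, build_lineage, run_tracker
from .cmtt import AdaptationConfig, adapt
from .jheads import HeadConfig, detect, train_joint_head
from .segnet import SegModel, TrainConfig, predict_mask, train_source
from .simdata import (SceneConfig, ShiftSpec, SyntheticSequence,
                      apply_domain_shift, generate_sequence)

__all__ = [
    "ExperimentConfig", "run_experiment", "cross_validate",
    "source_scene", "dense_shifted_target", "easy_tracking_scene",
    "default_shift", "label_components", "evaluate_segmentation",
    "evaluate_tracking", "segmentation_experiment", "tracking_experiment",
]


# ------------------------------------------------------- study conditions
def source_scene(seed: int, frame_size=(96, 96), n_cells: int = 6) -> SceneConfig:
    """Sparse, high-contrast source domain."""
    return SceneConfig(frame_size=frame_size, n_cells=n_cells,
                       cell_radius_range=(5, 8), intensity_fg=0.8,
                       intensity_bg=0.2, noise_sigma=0.02, motion_sigma=1.0,
                       n_frames=10, seed=seed)


def dense_shifted_target(seed: int, frame_size=(96, 96),
                         n_cells: int = 18) -> SceneConfig:
    """Target domain at three times the source density (before the
    photometric shift is applied)."""
    return SceneConfig(frame_size=frame_size, n_cells=n_cells,
                       cell_radius_range=(5, 8), intensity_fg=0.8,
                       intensity_bg=0.2, noise_sigma=0.02, motion_sigma=1.0,
                       n_frames=6, seed=seed)


def default_shift(seed: int) -> ShiftSpec:
    """Photometric domain shift: gamma compression, reduced contrast,
    darkening, an illumination plane and extra noise."""
    return ShiftSpec(gamma=2.5, contrast=0.45, brightness=-0.18,
                     illumination_gradient=0.3, noise_sigma=0.06, seed=seed)


def easy_tracking_scene(seed: int, n_frames: int = 20) -> SceneConfig:
    """Well-separated cells, low noise: the tracking sanity scenario."""
    return SceneConfig(frame_size=(128, 128), n_cells=10,
                       cell_radius_range=(7, 10), min_separation=26,
                       intensity_fg=0.8, intensity_bg=0.2, noise_sigma=0.02,
                       motion_sigma=0.8, n_frames=n_frames, seed=seed)


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str | None = None
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=10, learning_rate=3e-3, batch_size=4))
    adaptation: AdaptationConfig = field(default_factory=lambda: AdaptationConfig(
        patch_size=48, patch_overlap=16))
    head: HeadConfig = field(default_factory=lambda: HeadConfig(
        epochs=60, learning_rate=3e-3, embed_dim=32, hidden=16,
        score_threshold=0.45))
    association: AssociationConfig = field(default_factory=AssociationConfig)
    base_channels: int = 6
    iou_threshold: float = 0.5      # CLEAR matching gate
    # ablation switchboard
    use_cmtt: bool = True
    use_stage2: bool = True
    use_sa_reid: bool = True
    stage2_loss: str = "cmc"

    def resolved(self) -> dict:
        d = asdict(self)
        return d


# ------------------------------------------------------------- evaluation
def label_components(binary_mask: np.ndarray) -> np.ndarray:
    """Instance labels from a binary foreground mask (connected
    components, 8-connectivity)."""
    lab, _ = ndimage.label(np.asarray(binary_mask, dtype=bool),
                           structure=np.ones((3, 3), dtype=int))
    return lab.astype(np.uint16)


def evaluate_segmentation(prob_maps, gt_masks, threshold: float = 0.5) -> dict:
    """Mean Dice/IOU over frames plus object-level AJI of the
    connected-component labelling."""
    dices, ious, ajis = [], [], []
    for prob, gt in zip(prob_maps, gt_masks):
        pred = np.asarray(prob) >= threshold
        gt = np.asarray(gt)
        dices.append(metrics.dice(gt > 0, pred))
        ious.append(metrics.iou(gt > 0, pred))
        ajis.append(metrics.aji(gt, label_components(pred)))
    return {"dice": float(np.mean(dices)), "iou": float(np.mean(ious)),
            "aji": float(np.mean(ajis))}


def evaluate_tracking(tracklets, ref_masks, iou_threshold: float = 0.5) -> dict:
    pred = metrics.tracks_from_tracklets(tracklets)
    ref = metrics.tracks_from_masks(ref_masks)
    tm = metrics.match_tracks(pred, ref, iou_threshold)
    mt, ml = metrics.mt_ml(pred, ref, tm)
    return {"mota": metrics.mota(tm), "ct": metrics.complete_tracks(pred, ref, tm),
            "tf": metrics.track_fraction(pred, ref, tm), "mt": mt, "ml": ml,
            "fn": tm.fn, "fp": tm.fp, "idsw": tm.idsw, "gt": tm.gt}


# ------------------------------------------------------------ experiments
def segmentation_experiment(seed: int, cfg: ExperimentConfig | None = None) -> dict:
    """Source training + CMTT adaptation on the shifted dense target;
    reports Dice/IOU/AJI without adaptation, after Stage 1, and after the
    full two-stage aggregate."""
    cfg = cfg or ExperimentConfig()
    src = generate_sequence(source_scene(1000 + seed))
    model = SegModel(base_channels=cfg.base_channels, seed=seed)
    train_cfg = dataclasses.replace(cfg.train, seed=seed)
    train_source(model, (src.frames, src.instance_masks), train_cfg)
    tgt = generate_sequence(dense_shifted_target(2000 + seed))
    shift = default_shift(3000 + seed)
    timgs = [apply_domain_shift(f, shift) for f in tgt.frames]
    report = {"no_adapt": evaluate_segmentation(
        [predict_mask(model, im) for im in timgs], tgt.instance_masks)}
    if cfg.use_cmtt:
        acfg = dataclasses.replace(cfg.adaptation, seed=seed,
                                   stage2_loss=cfg.stage2_loss)
        res = adapt(copy.deepcopy(model), timgs, acfg,
                    use_stage2=cfg.use_stage2)
        report["stage1"] = evaluate_segmentation(res.pred1, tgt.instance_masks)
        report["adapted"] = evaluate_segmentation(res.final, tgt.instance_masks)
        report["logs"] = res.logs
    return report


def tracking_experiment(seed: int, cfg: ExperimentConfig | None = None,
                        scene: SceneConfig | None = None) -> dict:
    """Easy-scene tracking sanity: the segmentation unit and joint head
    train on the annotated video, then that recording is tracked and
    scored with MOTA/CT/TF/MT/ML.

    This is the one-shot deployment pattern (annotate a recording, fit,
    track it); the association stage never sees labels, so the scores
    exercise detection coherence, embedding quality and the matching
    logic rather than detector generalization (see the methods note)."""
    cfg = cfg or ExperimentConfig()
    seq = generate_sequence(scene or easy_tracking_scene(4000 + seed))
    model = SegModel(base_channels=cfg.base_channels, seed=seed)
    train_cfg = dataclasses.replace(cfg.train, seed=seed)
    train_source(model, (seq.frames, seq.instance_masks), train_cfg)
    head_cfg = dataclasses.replace(cfg.head, seed=seed,
                                   use_sam=cfg.use_sa_reid)
    head, _, _ = train_joint_head(model, seq.frames, seq.instance_masks,
                                  head_cfg)
    dets = [detect(model, head, f) for f in seq.frames]
    tracklets = run_tracker(dets, cfg.association)
    report = evaluate_tracking(tracklets, seq.instance_masks,
                               cfg.iou_threshold)
    report["lineage_rows"] = len(build_lineage(tracklets, cfg.association))
    return report


def crowded_tracking_scene(seed: int, n_frames: int = 15) -> SceneConfig:
    """Closer cells and faster motion: the regime where embedding quality
    decides identity preservation."""
    return SceneConfig(frame_size=(128, 128), n_cells=12,
                       cell_radius_range=(6, 8), min_separation=17,
                       intensity_fg=0.8, intensity_bg=0.2, noise_sigma=0.03,
                       motion_sigma=2.5, n_frames=n_frames, seed=seed)


def reid_ablation_experiment(seed: int,
                             cfg: ExperimentConfig | None = None) -> dict:
    """Spatial-attention ReID vs plain stacked-conv ReID on a crowded
    scene (same one-shot protocol as the tracking sanity experiment,
    shared backbone); reports tracking metrics per variant."""
    cfg = cfg or ExperimentConfig()
    seq = generate_sequence(crowded_tracking_scene(7000 + seed))
    model = SegModel(base_channels=cfg.base_channels, seed=seed)
    train_source(model, (seq.frames, seq.instance_masks),
                 dataclasses.replace(cfg.train, seed=seed))
    out = {}
    for name, use_sam in (("sa_reid", True), ("conv_reid", False)):
        head_cfg = dataclasses.replace(cfg.head, seed=seed, use_sam=use_sam)
        head, _, _ = train_joint_head(model, seq.frames, seq.instance_masks,
                                      head_cfg)
        dets = [detect(model, head, f) for f in seq.frames]
        tracklets = run_tracker(dets, cfg.association)
        out[name] = evaluate_tracking(tracklets, seq.instance_masks,
                                      cfg.iou_threshold)
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full pipeline under the ablation switchboard; returns (and
    optionally writes) the metrics report."""
    report = {
        "config": cfg.resolved(),
        "segmentation": segmentation_experiment(cfg.seed, cfg),
        "tracking": tracking_experiment(cfg.seed, cfg),
    }
    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def cross_validate(cfg: ExperimentConfig, k: int, n_sequences: int = 4) -> dict:
    """k-fold cross-validation over a pool of synthetic videos: train on
    the other folds' frames, evaluate segmentation on the held-out fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_sequences:
        raise ValueError("more folds than sequences")
    pool = [generate_sequence(easy_tracking_scene(6000 + cfg.seed * 97 + i,
                                                  n_frames=6))
            for i in range(n_sequences)]
    folds = np.array_split(np.arange(n_sequences), k)
    per_fold = []
    for fi, hold in enumerate(folds):
        train_idx = [i for i in range(n_sequences) if i not in hold]
        frames = [f for i in train_idx for f in pool[i].frames]
        masks = [m for i in train_idx for m in pool[i].instance_masks]
        model = SegModel(base_channels=cfg.base_channels, seed=cfg.seed + fi)
        train_source(model, (frames, masks),
                     dataclasses.replace(cfg.train, seed=cfg.seed + fi))
        test_frames = [f for i in hold for f in pool[i].frames]
        test_masks = [m for i in hold for m in pool[i].instance_masks]
        per_fold.append(evaluate_segmentation(
            [predict_mask(model, f) for f in test_frames], test_masks))
    agg = {key: {"mean": float(np.mean([r[key] for r in per_fold])),
                 "std": float(np.std([r[key] for r in per_fold]))}
           for key in per_fold[0]}
    return {"folds": per_fold, "aggregate": agg}
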