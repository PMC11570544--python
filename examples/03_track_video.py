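"""Full tracking in the one-shot deployment pattern: annotate a recording,
fit the segmentation unit and the joint detection + SA-ReID head on it,
then track that recording and score the result with MOTA / CT / TF.

MOTA near 1 means almost no misses, false alarms, or identity switches;
CT is the share of cell tracks reconstructed end-to-end by a single
predicted identity. The association stage never sees the labels."""

from cmttrack.assoc import build_lineage, run_tracker
from cmttrack.jheads import HeadConfig, detect, train_joint_head
from cmttrack.pipeline import easy_tracking_scene, evaluate_tracking
from cmttrack.segnet import SegModel, TrainConfig, train_source
from cmttrack.simdata import generate_sequence

seed = 2
seq = generate_sequence(easy_tracking_scene(seed))
model = SegModel(base_channels=6, seed=seed)
train_source(model, (seq.frames, seq.instance_masks),
             TrainConfig(epochs=10, learning_rate=3e-3, seed=seed))
head, id_map, hist = train_joint_head(
    model, seq.frames, seq.instance_masks,
    HeadConfig(epochs=60, learning_rate=3e-3, embed_dim=32, hidden=16,
               score_threshold=0.45, seed=seed))
print(f"joint loss (focal + CIOU + ReID): {hist[0]:.3f} -> {hist[-1]:.3f}")

detections = [detect(model, head, f) for f in seq.frames]
tracklets = run_tracker(detections)
report = evaluate_tracking(tracklets, seq.instance_masks)
print(f"MOTA {report['mota']:.3f}  CT {report['ct']:.2f}  TF {report['tf']:.2f}  "
      f"identity switches {report['idsw']}")
print("lineage table:", build_lineage(tracklets)[:5])
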