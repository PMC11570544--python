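"""Online association of per-frame detections into tracklets (JDE-style).

Two-pass matching per frame: (1) cosine distance between smoothed tracklet
embeddings and detection embeddings, gated by the motion prediction;
(2) IoU fallback for the remainder.  Both passes solve an optimal bipartite
assignment.  Motion is a constant-velocity Kalman filter on (x, y, w, h);
embeddings are exponentially smoothed with momentum 0.9; lost tracklets are
kept for a 10-frame patience window.  A best-effort lineage heuristic links
a new track to a track that ended the previous frame nearby (division).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .jheads import Detection, _iou

__all__ = ["AssociationConfig", "Tracklet", "associate_frame",
           "build_lineage", "run_tracker"]


@dataclass
class AssociationConfig:
    embedding_gate: float = 0.5     # max cosine distance in pass 1
    motion_gate: float = 24.0       # px; centre distance gate in pass 1
    iou_gate: float = 0.5           # min IoU in pass 2
    embed_momentum: float = 0.9
    patience: int = 10              # frames a lost tracklet survives
    division_gate: float = 20.0     # px; parent-link search radius


class _Kalman:
    """Constant-velocity filter on state (x, y, w, h, vx, vy)."""

    def __init__(self, box):
        x, y, w, h = box
        self.s = np.array([x, y, w, h, 0.0, 0.0])
        self.P = np.diag([4.0, 4.0, 4.0, 4.0, 25.0, 25.0])
        self.F = np.eye(6)
        self.F[0, 4] = self.F[1, 5] = 1.0
        self.Q = np.diag([1.0, 1.0, 0.5, 0.5, 1.0, 1.0])
        self.H = np.zeros((4, 6))
        self.H[:4, :4] = np.eye(4)
        self.R = np.diag([1.0, 1.0, 2.0, 2.0])

    def predict(self):
        self.s = self.F @ self.s
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.s[:4].copy()

    def update(self, box):
        z = np.asarray(box, dtype=np.float64)
        y = z - self.H @ self.s
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.s = self.s + K @ y
        self.P = (np.eye(6) - K @ self.H) @ self.P


@dataclass
class Tracklet:
    track_id: int
    start_frame: int
    boxes: dict = field(default_factory=dict)       # frame -> (x, y, w, h)
    embedding: np.ndarray | None = None
    status: str = "active"                          # active | lost | finished
    parent: int = 0
    lost_frames: int = 0
    kalman: _Kalman | None = None

    @property
    def end_frame(self):
        return max(self.boxes)

    @property
    def frames(self):
        return sorted(self.boxes)

    def update(self, frame: int, det: Detection, momentum: float):
        self.boxes[frame] = det.box
        self.status = "active"
        self.lost_frames = 0
        if self.kalman is None:
            self.kalman = _Kalman(det.box)
        else:
            self.kalman.update(det.box)
        if det.embedding is not None:
            if self.embedding is None:
                self.embedding = det.embedding.copy()
            else:
                e = momentum * self.embedding + (1 - momentum) * det.embedding
                self.embedding = e / (np.linalg.norm(e) + 1e-12)


def _cosine_dist(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - float(a @ b)


def _solve(cost: np.ndarray, gate: np.ndarray):
    """Optimal assignment on a gated cost matrix; returns accepted pairs."""
    big = 1e6
    masked = np.where(gate, cost, big)
    rows, cols = linear_sum_assignment(masked)
    return [(r, c) for r, c in zip(rows, cols) if gate[r, c]]


def associate_frame(tracklets: list[Tracklet], detections: list[Detection],
                    frame: int, next_id: int,
                    cfg: AssociationConfig = AssociationConfig()):
    """Match detections to live tracklets; returns (tracklets, next_id)."""
    live = [t for t in tracklets if t.status in ("active", "lost")]
    predicted = [t.kalman.predict() if t.kalman else np.array(t.boxes[t.end_frame])
                 for t in live]
    unmatched_t = list(range(len(live)))
    unmatched_d = list(range(len(detections)))
    # pass 1: embeddings, motion-gated
    if unmatched_t and unmatched_d:
        cost = np.zeros((len(unmatched_t), len(unmatched_d)))
        gate = np.zeros_like(cost, dtype=bool)
        for i, ti in enumerate(unmatched_t):
            t = live[ti]
            px, py = predicted[ti][:2]
            for j, di in enumerate(unmatched_d):
                d = detections[di]
                dist = np.hypot(d.x - px, d.y - py)
                c = (_cosine_dist(t.embedding, d.embedding)
                     if t.embedding is not None and d.embedding is not None
                     else 1.0)
                cost[i, j] = c
                gate[i, j] = (dist <= cfg.motion_gate
                              and c <= cfg.embedding_gate)
        pairs = _solve(cost, gate)
        for i, j in pairs:
            live[unmatched_t[i]].update(frame, detections[unmatched_d[j]],
                                        cfg.embed_momentum)
        matched_t = {unmatched_t[i] for i, _ in pairs}
        matched_d = {unmatched_d[j] for _, j in pairs}
        unmatched_t = [i for i in unmatched_t if i not in matched_t]
        unmatched_d = [j for j in unmatched_d if j not in matched_d]
    # pass 2: IoU fallback
    if unmatched_t and unmatched_d:
        cost = np.zeros((len(unmatched_t), len(unmatched_d)))
        gate = np.zeros_like(cost, dtype=bool)
        for i, ti in enumerate(unmatched_t):
            pbox = predicted[ti]
            for j, di in enumerate(unmatched_d):
                iou = _iou(tuple(pbox), detections[di].box)
                cost[i, j] = 1.0 - iou
                gate[i, j] = iou >= cfg.iou_gate
        pairs = _solve(cost, gate)
        for i, j in pairs:
            live[unmatched_t[i]].update(frame, detections[unmatched_d[j]],
                                        cfg.embed_momentum)
        matched_t = {unmatched_t[i] for i, _ in pairs}
        matched_d = {unmatched_d[j] for _, j in pairs}
        unmatched_t = [i for i in unmatched_t if i not in matched_t]
        unmatched_d = [j for j in unmatched_d if j not in matched_d]
    # bookkeeping
    for ti in unmatched_t:
        t = live[ti]
        t.status = "lost"
        t.lost_frames += 1
        if t.lost_frames > cfg.patience:
            t.status = "finished"
    for di in unmatched_d:
        t = Tracklet(next_id, frame)
        t.update(frame, detections[di], cfg.embed_momentum)
        tracklets.append(t)
        next_id += 1
    return tracklets, next_id


def build_lineage(tracklets: list[Tracklet],
                  cfg: AssociationConfig = AssociationConfig()):
    """CTC-style track table (label, begin, end, parent).

    Division is recovered heuristically (online association does not model
    it explicitly).  A tracklet starting at frame b is linked to a parent
    that either ended at b-1 nearby, or is a nearby tracklet whose box area
    roughly halved at b — the signature of the tracker carrying the parent
    identity onto one daughter.  In the latter case the parent tracklet is
    split at b so the table keeps CTC parent semantics (a parent ends the
    frame before its children begin).
    """
    tracks = {t.track_id: dict(t.boxes) for t in tracklets}
    parent_of = {tid: 0 for tid in tracks}
    next_label = max(tracks, default=0) + 1
    splits: list[tuple[int, int, int]] = []   # (frame, parent id, new-track id)
    for t in sorted(tracklets, key=lambda t: t.track_id):
        begin = min(t.boxes)
        if begin == 0:
            continue
        x0, y0 = t.boxes[begin][:2]
        # candidates that ended right before this track began
        best_d, parent = cfg.division_gate, 0
        for c in tracklets:
            if c.track_id == t.track_id or c.end_frame != begin - 1:
                continue
            cx, cy = c.boxes[begin - 1][:2]
            d = np.hypot(cx - x0, cy - y0)
            if d < best_d:
                best_d, parent = d, c.track_id
        if parent:
            parent_of[t.track_id] = parent
            continue
        # continuation split: a nearby live track whose area halved at b
        best_d = cfg.division_gate
        chosen = None
        for c in tracklets:
            if c.track_id == t.track_id:
                continue
            if begin - 1 not in c.boxes or begin not in c.boxes:
                continue
            aw, ah = c.boxes[begin - 1][2:]
            bw, bh = c.boxes[begin][2:]
            if bw * bh > 0.75 * aw * ah:
                continue
            cx, cy = c.boxes[begin - 1][:2]
            d = np.hypot(cx - x0, cy - y0)
            if d < best_d:
                best_d, chosen = d, c.track_id
        if chosen is not None:
            splits.append((begin, chosen, t.track_id))
    done = set()
    for begin, pid, nid in splits:
        if pid in done:
            parent_of[nid] = pid
            continue
        done.add(pid)
        boxes = tracks[pid]
        child = {f: b for f, b in boxes.items() if f >= begin}
        remain = {f: b for f, b in boxes.items() if f < begin}
        if not child or not remain:
            continue
        tracks[pid] = remain
        tracks[next_label] = child
        parent_of[next_label] = pid
        parent_of[nid] = pid
        next_label += 1
    return [(tid, min(b), max(b), parent_of[tid])
            for tid, b in sorted(tracks.items()) if b]


def run_tracker(detections_per_frame: list[list[Detection]],
                cfg: AssociationConfig = AssociationConfig()):
    """Associate a whole sequence of detection lists into tracklets."""
    tracklets: list[Tracklet] = []
    next_id = 1
    for f, dets in enumerate(detections_per_frame):
        tracklets, next_id = associate_frame(tracklets, dets, f, next_id, cfg)
    return tracklets
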