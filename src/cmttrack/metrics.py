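"""Segmentation and tracking metrics: Dice, IOU, AJI at pixel/object level;
MOTA, complete tracks (CT), track fraction (TF), MT/ML at sequence level;
and the cell-imaging-density statistic.

Track-level metrics use CLEAR-style persistent matching: a reference object
keeps its previous predicted partner while the IoU stays above threshold,
remaining objects are matched by optimal assignment, and identity switches
are counted when a reference changes partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "dice", "iou", "aji", "TrackMatch", "match_tracks", "mota",
    "complete_tracks", "track_fraction", "mt_ml", "cell_imaging_density",
    "tracks_from_masks", "tracks_from_tracklets", "box_iou",
]


# ------------------------------------------------------------ segmentation
def dice(g, s) -> float:
    """2|G∩S| / (|G| + |S|); both empty -> 1 by convention."""
    g = np.asarray(g, dtype=bool)
    s = np.asarray(s, dtype=bool)
    if g.shape != s.shape:
        raise ValueError("mask shapes differ")
    denom = g.sum() + s.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (g & s).sum() / denom)


def iou(g, s) -> float:
    """|G∩S| / |G∪S|; both empty -> 1 by convention."""
    g = np.asarray(g, dtype=bool)
    s = np.asarray(s, dtype=bool)
    if g.shape != s.shape:
        raise ValueError("mask shapes differ")
    union = (g | s).sum()
    if union == 0:
        return 1.0
    return float((g & s).sum() / union)


def aji(g_inst, s_inst) -> float:
    """Aggregated Jaccard index over instance masks.

    Each ground-truth object G_i selects the prediction S_i maximizing
    their Jaccard index (ties: lower label); predictions never selected
    form the unmatched set R whose pixels inflate the denominator.
    """
    g_inst = np.asarray(g_inst)
    s_inst = np.asarray(s_inst)
    g_labels = [l for l in np.unique(g_inst) if l != 0]
    if not g_labels:
        raise ValueError("no ground-truth objects")
    s_labels = [l for l in np.unique(s_inst) if l != 0]
    inter_sum = 0
    union_sum = 0
    used = set()
    for gl in g_labels:
        gmask = g_inst == gl
        best_j, best_l, best_i, best_u = -1.0, None, 0, gmask.sum()
        for sl in s_labels:
            smask = s_inst == sl
            inter = (gmask & smask).sum()
            if inter == 0:
                continue
            union = gmask.sum() + smask.sum() - inter
            j = inter / union
            if j > best_j or (j == best_j and best_l is not None and sl < best_l):
                best_j, best_l, best_i, best_u = j, sl, inter, union
        inter_sum += best_i
        union_sum += best_u
        if best_l is not None:
            used.add(best_l)
    extra = sum((s_inst == sl).sum() for sl in s_labels if sl not in used)
    return float(inter_sum / (union_sum + extra))


# ----------------------------------------------------------------- tracking
def box_iou(a, b) -> float:
    """IoU of two centre-format boxes (x, y, w, h)."""
    ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax2, ay2 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx2, by2 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


@dataclass
class TrackMatch:
    """Frame-level correspondence between predicted and reference tracks."""

    fn: int = 0
    fp: int = 0
    idsw: int = 0
    gt: int = 0
    matches: dict = field(default_factory=dict)  # frame -> {ref_id: pred_id}


def tracks_from_masks(masks) -> dict:
    """Reference tracks {id: {frame: (x, y, w, h)}} from instance masks."""
    tracks: dict = {}
    for f, mask in enumerate(masks):
        mask = np.asarray(mask)
        for lab in np.unique(mask):
            if lab == 0:
                continue
            ys, xs = np.nonzero(mask == lab)
            box = (float(xs.mean()), float(ys.mean()),
                   float(xs.max() - xs.min() + 1), float(ys.max() - ys.min() + 1))
            tracks.setdefault(int(lab), {})[f] = box
    return tracks


def tracks_from_tracklets(tracklets) -> dict:
    return {t.track_id: dict(t.boxes) for t in tracklets}


def match_tracks(pred_tracks: dict, ref_tracks: dict,
                 iou_threshold: float = 0.5) -> TrackMatch:
    """CLEAR-style persistent matching over all frames."""
    frames = sorted({f for t in ref_tracks.values() for f in t}
                    | {f for t in pred_tracks.values() for f in t})
    tm = TrackMatch()
    last_partner: dict = {}
    for f in frames:
        refs = {rid: t[f] for rid, t in ref_tracks.items() if f in t}
        preds = {pid: t[f] for pid, t in pred_tracks.items() if f in t}
        tm.gt += len(refs)
        frame_match: dict = {}
        # keep persistent partners when still overlapping
        for rid in list(refs):
            pid = last_partner.get(rid)
            if pid is not None and pid in preds \
                    and box_iou(refs[rid], preds[pid]) >= iou_threshold:
                frame_match[rid] = pid
                del preds[pid]
                del refs[rid]
        # optimal assignment for the rest
        if refs and preds:
            rids = list(refs)
            pids = list(preds)
            cost = np.ones((len(rids), len(pids)))
            gate = np.zeros_like(cost, dtype=bool)
            for i, rid in enumerate(rids):
                for j, pid in enumerate(pids):
                    v = box_iou(refs[rid], preds[pid])
                    cost[i, j] = 1.0 - v
                    gate[i, j] = v >= iou_threshold
            rows, cols = linear_sum_assignment(np.where(gate, cost, 1e6))
            for i, j in zip(rows, cols):
                if gate[i, j]:
                    rid, pid = rids[i], pids[j]
                    frame_match[rid] = pid
                    del preds[pid]
                    refs.pop(rid)
        tm.fn += len(refs)
        tm.fp += len(preds)
        for rid, pid in frame_match.items():
            if rid in last_partner and last_partner[rid] != pid:
                tm.idsw += 1
            last_partner[rid] = pid
        tm.matches[f] = frame_match
    return tm


def mota(match: TrackMatch) -> float:
    """1 - (FN + FP + IDSW) / GT; may be negative."""
    if match.gt == 0:
        raise ValueError("no ground-truth objects in the sequence")
    return 1.0 - (match.fn + match.fp + match.idsw) / match.gt


def complete_tracks(pred_tracks: dict, ref_tracks: dict,
                    match: TrackMatch | None = None,
                    iou_threshold: float = 0.5) -> float:
    """Fraction of reference tracks reconstructed over their whole span by
    a single predicted track."""
    if not ref_tracks:
        raise ValueError("no reference tracks")
    match = match or match_tracks(pred_tracks, ref_tracks, iou_threshold)
    complete = 0
    for rid, t in ref_tracks.items():
        partners = {match.matches.get(f, {}).get(rid) for f in t}
        if None not in partners and len(partners) == 1:
            complete += 1
    return complete / len(ref_tracks)


def track_fraction(pred_tracks: dict, ref_tracks: dict,
                   match: TrackMatch | None = None,
                   iou_threshold: float = 0.5) -> float:
    """Mean over detected reference tracks of (longest continuous run
    matched by one predicted track) / (reference length).  Undetected
    references are excluded; returns NaN if none is detected."""
    match = match or match_tracks(pred_tracks, ref_tracks, iou_threshold)
    fractions = []
    for rid, t in ref_tracks.items():
        span = sorted(t)
        partners = [match.matches.get(f, {}).get(rid) for f in span]
        if all(p is None for p in partners):
            continue
        best = run = 0
        prev = None
        for p in partners:
            run = run + 1 if (p is not None and p == prev) else (1 if p is not None else 0)
            prev = p
            best = max(best, run)
        fractions.append(best / len(span))
    return float(np.mean(fractions)) if fractions else float("nan")


def mt_ml(pred_tracks: dict, ref_tracks: dict,
          match: TrackMatch | None = None,
          iou_threshold: float = 0.5) -> tuple[float, float]:
    """(MT %, ML %): share of reference tracks matched in >= 80% / < 20%
    of their frames."""
    match = match or match_tracks(pred_tracks, ref_tracks, iou_threshold)
    mt = ml = 0
    for rid, t in ref_tracks.items():
        cov = sum(1 for f in t if match.matches.get(f, {}).get(rid) is not None)
        ratio = cov / len(t)
        if ratio >= 0.8:
            mt += 1
        elif ratio < 0.2:
            ml += 1
    n = len(ref_tracks)
    return 100.0 * mt / n, 100.0 * ml / n


# ------------------------------------------------------------------ density
def cell_imaging_density(mask, effective_area: float | None = None,
                         margin: float | None = None) -> dict:
    """Cell-imaging-density statistic, reported in both conventions.

    ``area_per_cell`` is effective area / cell count as printed;
    ``cells_per_kilopixel`` is the reciprocal reading (cells per 1000 px of
    effective area), which increases with crowding.  The effective area
    defaults to the frame minus a margin of one typical cell radius.
    """
    mask = np.asarray(mask)
    n_cells = len([l for l in np.unique(mask) if l != 0])
    if n_cells == 0:
        raise ValueError("no cells in mask")
    if effective_area is None:
        if margin is None:
            sizes = [np.sqrt((mask == l).sum() / np.pi)
                     for l in np.unique(mask) if l != 0]
            margin = float(np.mean(sizes))
        h, w = mask.shape
        effective_area = max(h - 2 * margin, 1) * max(w - 2 * margin, 1)
    return {
        "area_per_cell": float(effective_area / n_cells),
        "cells_per_kilopixel": float(1000.0 * n_cells / effective_area),
        "n_cells": n_cells,
        "effective_area": float(effective_area),
    }
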