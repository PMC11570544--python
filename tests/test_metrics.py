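"""Metric suite vs brute-force oracles and hand-built cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmttrack import metrics
from cmttrack.metrics import (TrackMatch, aji, cell_imaging_density,
                              complete_tracks, dice, iou, match_tracks, mota,
                              mt_ml, track_fraction)


# ------------------------------------------------------------ pixel level
def test_dice_iou_basic_cases():
    a = np.zeros((10, 10), bool)
    a[:5] = True
    assert dice(a, a) == 1.0 and iou(a, a) == 1.0
    b = np.zeros((10, 10), bool)
    b[5:] = True
    assert dice(a, b) == 0.0 and iou(a, b) == 0.0
    assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0
    with pytest.raises(ValueError):
        dice(np.zeros((3, 3)), np.zeros((4, 4)))


def test_dice_half_overlap():
    g = np.zeros(200, bool)
    s = np.zeros(200, bool)
    g[:100] = True
    s[50:150] = True
    assert dice(g, s) == pytest.approx(0.5)
    assert iou(g, s) == pytest.approx(1 / 3)


@given(st.integers(0, 2 ** 24 - 1))
@settings(max_examples=50, deadline=None)
def test_dice_iou_identity_relation(bits):
    g = np.array([(bits >> i) & 1 for i in range(12)], dtype=bool)
    s = np.array([(bits >> i) & 1 for i in range(12, 24)], dtype=bool)
    d, j = dice(g, s), iou(g, s)
    assert d == pytest.approx(2 * j / (1 + j))
    assert d >= j
    if d == j:
        assert d in (0.0, 1.0)


# ------------------------------------------------------------------- AJI
def _aji_oracle(g, s):
    """Literal brute-force evaluation of the aggregated Jaccard index."""
    gl = [l for l in np.unique(g) if l]
    sl = [l for l in np.unique(s) if l]
    num = den = 0
    used = set()
    for glab in gl:
        gm = g == glab
        cands = []
        for slab in sl:
            sm = s == slab
            inter = (gm & sm).sum()
            union = (gm | sm).sum()
            cands.append((inter / union if union else 0.0, int(slab), inter, union))
        best = max(cands, key=lambda t: (t[0], -t[1])) if cands else None
        if best and best[2] > 0:
            num += best[2]
            den += best[3]
            used.add(best[1])
        else:
            den += gm.sum()
    for slab in sl:
        if slab not in used:
            den += (s == slab).sum()
    return num / den


def test_aji_perfect_and_merged():
    g = np.zeros((10, 10), np.uint16)
    g[0:2, 0:5] = 1   # 10 px
    g[4:6, 0:5] = 2   # 10 px
    assert aji(g, g) == 1.0
    merged = np.zeros_like(g)
    merged[(g == 1) | (g == 2)] = 1
    # one 20-px prediction covering both 10-px objects exactly:
    # best match for each G_i has |∩|=10, |∪|=20; no unmatched predictions
    assert aji(g, merged) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        aji(np.zeros((5, 5)), merged)


def test_aji_matches_bruteforce_on_random_labelings(rng):
    for _ in range(25):
        g = rng.integers(0, 4, size=(12, 12)).astype(np.uint16)
        s = rng.integers(0, 4, size=(12, 12)).astype(np.uint16)
        if not (g > 0).any():
            g[0, 0] = 1
        assert aji(g, s) == pytest.approx(_aji_oracle(g, s), abs=1e-12)


def test_aji_more_stringent_than_iou(rng):
    for _ in range(10):
        g = rng.integers(0, 4, size=(16, 16)).astype(np.uint16)
        s = rng.integers(0, 4, size=(16, 16)).astype(np.uint16)
        if not (g > 0).any():
            g[0, 0] = 1
        assert aji(g, s) <= iou(g > 0, s > 0) + 1e-12


# ------------------------------------------------------------------ MOTA
def test_mota_formula_cases():
    assert mota(TrackMatch(fn=0, fp=0, idsw=0, gt=10)) == 1.0
    assert mota(TrackMatch(fn=2, fp=1, idsw=1, gt=20)) == pytest.approx(0.8)
    assert mota(TrackMatch(fn=20, fp=0, idsw=0, gt=20)) == 0.0
    with pytest.raises(ValueError):
        mota(TrackMatch(gt=0))


def _track(frames, x0, step=0.0, w=10):
    return {f: (x0 + step * i, 20.0, w, w) for i, f in enumerate(frames)}


def test_match_tracks_counts_switches():
    ref = {1: _track(range(10), 20)}
    # prediction covers the span with two different ids
    pred = {1: _track(range(5), 20), 2: _track(range(5, 10), 20)}
    tm = match_tracks(pred, ref)
    assert tm.fn == 0 and tm.fp == 0 and tm.idsw == 1
    assert mota(tm) == pytest.approx(0.9)


def test_complete_tracks_fraction():
    ref = {1: _track(range(6), 20), 2: _track(range(6), 60),
           3: _track(range(6), 100), 4: _track(range(6), 140)}
    pred = {1: _track(range(6), 20), 2: _track(range(6), 60),
            3: _track(range(3), 100)}  # track 3 partial, track 4 missing
    tm = match_tracks(pred, ref)
    assert complete_tracks(pred, ref, tm) == pytest.approx(0.5)
    # a mid-span identity switch disqualifies a track from CT
    pred_sw = {1: _track(range(3), 20), 5: _track(range(3, 6), 20)}
    ref_one = {1: _track(range(6), 20)}
    assert complete_tracks(pred_sw, ref_one) == 0.0
    with pytest.raises(ValueError):
        complete_tracks(pred, {})


def test_track_fraction_run_lengths():
    ref = {1: _track(range(10), 20)}
    pred = {1: _track(range(7), 20), 2: _track(range(7, 10), 20)}
    assert track_fraction(pred, ref) == pytest.approx(0.7)
    assert track_fraction(ref, ref) == 1.0
    # undetected reference tracks are excluded from the average
    ref2 = {1: _track(range(10), 20), 2: _track(range(10), 200)}
    assert track_fraction(pred, ref2) == pytest.approx(0.7)
    assert np.isnan(track_fraction({}, ref))


def _tf_oracle(partners):
    best = run = 0
    prev = None
    for p in partners:
        run = run + 1 if (p is not None and p == prev) else (1 if p else 0)
        prev = p
        best = max(best, run)
    return best


def test_track_fraction_three_track_oracle():
    ref = {1: _track(range(8), 20), 2: _track(range(8), 60),
           3: _track(range(8), 100)}
    pred = {1: _track(range(4), 20), 9: _track(range(4, 8), 20),
            2: _track(range(8), 60),
            3: _track(range(2), 100), 7: _track(range(3, 8), 100)}
    tm = match_tracks(pred, ref)
    runs = []
    for rid in ref:
        partners = [tm.matches.get(f, {}).get(rid) for f in sorted(ref[rid])]
        runs.append(_tf_oracle(partners) / len(ref[rid]))
    assert track_fraction(pred, ref, tm) == pytest.approx(np.mean(runs))


def test_mt_ml_thresholds():
    ref = {1: _track(range(10), 20), 2: _track(range(10), 60),
           3: _track(range(10), 100)}
    pred = {1: _track(range(9), 20),          # 90% -> MT
            2: _track(range(1), 60),          # 10% -> ML
            3: _track(range(5), 100)}         # 50% -> neither
    mt, ml = mt_ml(pred, ref)
    assert mt == pytest.approx(100 / 3)
    assert ml == pytest.approx(100 / 3)


def test_ideal_input_maxes_every_metric():
    ref = {i: _track(range(10), 20 + 40 * i) for i in range(4)}
    tm = match_tracks(ref, ref)
    assert mota(tm) == 1.0
    assert complete_tracks(ref, ref, tm) == 1.0
    assert track_fraction(ref, ref, tm) == 1.0
    assert mt_ml(ref, ref, tm) == (100.0, 0.0)


# ---------------------------------------------------------------- density
def test_density_conventions():
    mask = np.zeros((40, 40), np.uint16)
    for i in range(10):
        mask[(i // 5) * 4:(i // 5) * 4 + 2, (i % 5) * 4:(i % 5) * 4 + 2] = i + 1
    d = cell_imaging_density(mask, effective_area=1000.0)
    assert d["area_per_cell"] == pytest.approx(100.0)
    assert d["cells_per_kilopixel"] == pytest.approx(10.0)
    # doubling the cells at fixed area halves the printed convention
    mask2 = mask.copy()
    for i in range(10):
        mask2[20 + (i // 5) * 4:20 + (i // 5) * 4 + 2,
              (i % 5) * 4:(i % 5) * 4 + 2] = 11 + i
    d2 = cell_imaging_density(mask2, effective_area=1000.0)
    assert d2["area_per_cell"] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        cell_imaging_density(np.zeros((8, 8), np.uint16))
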