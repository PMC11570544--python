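"""CMTT losses, patching, BN-only modulation, and the two adaptation
stages."""

import copy
import logging

import numpy as np
import pytest

from cmttrack import cmtt
from cmttrack.nn import Tensor
from cmttrack.segnet import SegModel, predict_mask


# ----------------------------------------------------------------- entropy
def test_entropy_known_values():
    assert cmtt.shannon_entropy_loss(np.array([[0.5, 0.5]])) == pytest.approx(
        np.log(2), abs=1e-9)
    assert cmtt.shannon_entropy_loss(np.array([[1.0, 0.0]])) == pytest.approx(0.0)
    # direct arithmetic: -(0.9 ln 0.9 + 0.1 ln 0.1)
    assert cmtt.shannon_entropy_loss(np.array([[0.9, 0.1]])) == pytest.approx(
        0.32508, abs=1e-5)
    with pytest.raises(ValueError):
        cmtt.shannon_entropy_loss(np.array([[-0.1, 1.1]]))


def test_entropy_bounds_at_onehot_and_uniform(rng):
    n, c = 50, 3
    onehot = np.eye(c)[rng.integers(0, c, n)]
    assert cmtt.shannon_entropy_loss(onehot) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((n, c), 1.0 / c)
    assert cmtt.shannon_entropy_loss(uniform) == pytest.approx(np.log(c))
    mixed = rng.dirichlet(np.ones(c), size=n)
    assert 0 <= cmtt.shannon_entropy_loss(mixed) <= np.log(c) + 1e-12


# --------------------------------------------------------------------- BNM
def test_bnm_known_and_oracle(rng):
    assert cmtt.bnm_loss(np.eye(2)) == pytest.approx(-1.0)
    b = 7
    rows = np.tile(np.array([[0.0, 1.0]]), (b, 1))
    assert cmtt.bnm_loss(rows) == pytest.approx(-1.0 / np.sqrt(b))
    for _ in range(20):
        a = rng.normal(size=(rng.integers(2, 16), rng.integers(2, 8)))
        oracle = -np.linalg.svd(a, compute_uv=False).sum() / a.shape[0]
        assert cmtt.bnm_loss(a) == pytest.approx(oracle, abs=1e-6)
    with pytest.raises(ValueError):
        cmtt.bnm_loss(np.array([[np.nan, 1.0]]))


def test_entire_image_loss_affine_in_alpha(rng):
    probs = rng.dirichlet(np.ones(2), size=30)
    ls = cmtt.shannon_entropy_loss(probs)
    lb = cmtt.bnm_loss(probs)
    assert cmtt.entire_image_loss(probs, probs, 0.0) == pytest.approx(ls)
    vals = [cmtt.entire_image_loss(probs, probs, a) for a in (0.0, 0.5, 1.0)]
    assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2)
    assert vals[1] == pytest.approx(ls + 0.5 * lb)
    with pytest.raises(ValueError):
        cmtt.entire_image_loss(probs, probs, -0.1)


# -------------------------------------------------------------- similarity
@pytest.mark.parametrize("i,j,expected", [
    (0.3, 0.3, 1.0), (0.0, 1.0, 0.5), (0.0, np.sqrt(3), 0.25),
])
def test_similarity_values(i, j, expected):
    assert cmtt.similarity(i, j) == pytest.approx(expected)


# ------------------------------------------------------------------ center
def test_compute_center_modes_and_fallback(caplog):
    patch = np.array([0.1, 0.2, 0.3, 0.9])
    mask = np.array([False, False, False, True])
    assert cmtt.compute_center(patch, mask, "median").delta == pytest.approx(0.2)
    assert cmtt.compute_center(patch, mask, "mean").delta == pytest.approx(0.2)
    with caplog.at_level(logging.WARNING, logger="cmttrack.cmtt"):
        c = cmtt.compute_center(patch, np.ones(4, bool), "median", fallback=0.15)
    assert c.fallback_used and c.delta == pytest.approx(0.15)
    assert any("global background" in r.message for r in caplog.records)


# --------------------------------------------------------------------- CMC
def test_cmc_loss_printed_form():
    # balanced numerator and denominator halves -> log 2
    px = np.array([0.5, 0.5, 0.7, 0.7])
    val = cmtt.cmc_loss(px, np.array([0, 1]), np.array([2, 3]), delta=0.6)
    assert val == pytest.approx(np.log(2))
    # empty background -> -log 1 = 0
    assert cmtt.cmc_loss(px, np.arange(4), np.array([], dtype=int), 0.5) == 0.0
    with pytest.raises(cmtt.EmptyForegroundError):
        cmtt.cmc_loss(px, np.array([], dtype=int), np.arange(4), 0.5)


def test_cmc_loss_matches_independent_formula(rng):
    for _ in range(50):
        n = rng.integers(4, 30)
        px = rng.uniform(size=n)
        fg = rng.uniform(size=n) > 0.5
        if not fg.any():
            fg[0] = True
        delta = float(rng.uniform())
        phi = 1.0 / (1.0 + (px - delta) ** 2)
        sp = np.exp(phi[fg]).sum()
        sm = np.exp(phi[~fg]).sum()
        oracle = -np.log(sp / (sp + sm))
        val = cmtt.cmc_loss(px, np.flatnonzero(fg), np.flatnonzero(~fg), delta)
        assert val == pytest.approx(oracle, abs=1e-9)


def test_cmc_decreases_as_background_moves_from_center():
    px = np.array([0.5, 0.5, 0.45])
    base = cmtt.cmc_loss(px, np.array([0, 1]), np.array([2]), delta=0.5)
    moved = px.copy()
    moved[2] = 0.95   # background pixel moves away from delta
    far = cmtt.cmc_loss(moved, np.array([0, 1]), np.array([2]), delta=0.5)
    assert far < base


def test_cmc_soft_reduces_to_printed_on_binary_memberships(rng):
    px = rng.uniform(size=12)
    fg = rng.uniform(size=12) > 0.4
    fg[0] = True
    delta = 0.3
    phi = 1.0 / (1.0 + (px - delta) ** 2)
    hard = cmtt.cmc_loss(px, np.flatnonzero(fg), np.flatnonzero(~fg), delta)
    soft = cmtt.cmc_loss_soft(Tensor(fg.astype(float)), phi).item()
    assert soft == pytest.approx(hard, abs=1e-9)


# ----------------------------------------------------------------- patches
def test_patch_grid_counts_and_errors():
    assert len(cmtt.split_patches(np.zeros((256, 256)), 128, 0).patches) == 4
    assert len(cmtt.split_patches(np.zeros((256, 256)), 128, 64).patches) == 9
    with pytest.raises(ValueError):
        cmtt.split_patches(np.zeros((64, 64)), 32, 32)
    with pytest.raises(ValueError):
        cmtt.split_patches(np.zeros((64, 64)), 8, 0)


def test_patch_coverage_and_stitch_identity(rng):
    for size, ps, ov in ((96, 48, 16), (100, 48, 12), (64, 48, 24)):
        full = rng.uniform(size=(size, size))
        grid = cmtt.split_patches(full, ps, ov)
        covered = np.zeros((size, size), dtype=int)
        for r0, c0, h, w in grid.patches:
            covered[r0:r0 + h, c0:c0 + w] += 1
        assert (covered > 0).all()
        crops = [full[r: r + h, c: c + w] for (r, c, h, w) in grid.patches]
        np.testing.assert_allclose(cmtt.stitch_patches(grid, crops), full,
                                   atol=1e-12)


# -------------------------------------------------------------- adaptation
def test_adaptable_parameters_are_bn_affine_only():
    model = SegModel(base_channels=4, seed=0)
    params = cmtt.adaptable_parameters(model)
    assert all(p.bn_affine for p in params)
    from cmttrack.nn import BatchNorm2d
    n_features = sum(m.gamma.data.size for m in model.modules()
                     if isinstance(m, BatchNorm2d))
    assert sum(p.data.size for p in params) == 2 * n_features


def test_stage1_zero_epochs_is_identity(trained_model, tiny_sequence):
    model = copy.deepcopy(trained_model)
    cfg = cmtt.AdaptationConfig(stage1_epochs=0, stage2_epochs=0)
    model, pred1, _ = cmtt.adapt_stage1(model, tiny_sequence.frames[:2], cfg)
    for img, p in zip(tiny_sequence.frames[:2], pred1):
        np.testing.assert_array_equal(p, predict_mask(trained_model, img))


def test_bn_freeze_contract_and_stat_shift(trained_model, tiny_sequence):
    model = copy.deepcopy(trained_model)
    before = {name: p.data.copy() for name, p in model.named_parameters()
              if not p.bn_affine}
    stats_before = [m.running_mean.copy() for m in model.modules()
                    if hasattr(m, "running_mean")]
    shifted = [np.clip(f * 0.4 + 0.3, 0, 1) for f in tiny_sequence.frames[:4]]
    cfg = cmtt.AdaptationConfig(stage1_epochs=2, stage2_epochs=1,
                                patch_size=32, patch_overlap=8, batch_size=2)
    result = cmtt.adapt(model, shifted, cfg)
    after = dict(result.model.named_parameters())
    for name, data in before.items():
        assert np.array_equal(after[name].data, data), name
    stats_after = [m.running_mean.copy() for m in result.model.modules()
                   if hasattr(m, "running_mean")]
    assert any(not np.allclose(a, b)
               for a, b in zip(stats_before, stats_after))


def test_stage2_all_background_raises(trained_model):
    model = copy.deepcopy(trained_model)
    # a target whose Stage-1 prediction is empty everywhere
    blank = [np.zeros((64, 64)) for _ in range(2)]
    pred1 = [np.zeros((64, 64)) for _ in range(2)]
    cfg = cmtt.AdaptationConfig(patch_size=32, patch_overlap=0)
    with pytest.raises(cmtt.AllPatchesSkippedError):
        cmtt.adapt_stage2(model, blank, pred1, cfg)


def test_stage1_loss_descends(trained_model, tiny_sequence):
    model = copy.deepcopy(trained_model)
    shifted = [np.clip(f ** 2.0 * 0.6, 0, 1) for f in tiny_sequence.frames[:4]]
    cfg = cmtt.AdaptationConfig(stage1_epochs=4, stage2_epochs=0,
                                learning_rate=1e-3, batch_size=4)
    _, _, log = cmtt.adapt_stage1(model, shifted, cfg)
    assert log["epoch_losses"][-1] <= log["epoch_losses"][0]


# ------------------------------------------------------------- aggregation
def test_aggregate_endpoints_and_midpoint():
    p1 = np.full((4, 4), 0.2)
    p2 = np.full((4, 4), 0.6)
    np.testing.assert_array_equal(cmtt.aggregate_predictions(p1, p2, 1.0), p1)
    np.testing.assert_array_equal(cmtt.aggregate_predictions(p1, p2, 0.0), p2)
    np.testing.assert_allclose(cmtt.aggregate_predictions(p1, p2, 0.5), 0.4)
    with pytest.raises(ValueError):
        cmtt.aggregate_predictions(p1, p2, 1.5)
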