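"""Masking accounting, loss oracles, and training-loop contracts."""

import numpy as np
import pytest

from beast import (SceneConfig, generate_scene, make_mask, mae_loss,
                   info_nce_loss, total_loss, pretrain)
from beast.backbone import EncoderConfig
from beast.nn import Tensor
from beast.pretraining import LossConfig, MaskPlan
from beast.video_data import ContrastiveBatch, FrameRecord


def make_synthetic_batch(B):
    """A structurally valid batch (images unused by the loss)."""
    frames, anchors, pos = [], [], {}
    for i in range(B // 2):
        frames.append(FrameRecord(f"v{i}", 100, None))
        frames.append(FrameRecord(f"v{i}", 101, None))
        anchors.append(2 * i)
        pos[2 * i] = 2 * i + 1
    return ContrastiveBatch(frames, anchors, pos,
                            [(f.video_id, f.t) for f in frames])


# ------------------------------------------------------------------- masking

def test_mask_counts_at_canonical_ratio():
    plan = make_mask(196, 0.75, seed=0)
    assert plan.L == 49
    assert plan.mask.sum() == 147


def test_zero_ratio_masks_nothing():
    plan = make_mask(16, 0.0, seed=0)
    assert plan.L == 16 and not plan.mask.any()


def test_mask_positions_uniform_over_seeds():
    freq = np.zeros(16)
    n = 10_000
    for s in range(n):
        freq += make_mask(16, 0.75, seed=s).mask
    freq /= n
    se = np.sqrt(0.75 * 0.25 / n)
    assert (np.abs(freq - 0.75) < 3 * se).all()


def test_mask_ratio_bounds():
    with pytest.raises(ValueError):
        make_mask(16, 1.0, seed=0)
    with pytest.raises(ValueError):
        make_mask(16, -0.1, seed=0)


# ----------------------------------------------------------------- MAE loss

def test_mae_loss_zero_on_perfect_reconstruction(rng):
    xp = rng.uniform(size=(8, 12))
    plan = make_mask(8, 0.5, seed=0)
    assert mae_loss(xp, xp.copy(), plan, "masked_only") == 0.0
    assert mae_loss(xp, xp.copy(), plan, "all_patches") == 0.0


def test_mae_loss_per_element_mean_convention():
    xp = np.zeros((1, 6))
    xhat = np.ones((1, 6))
    plan = MaskPlan(mask=np.array([True]), ratio=1.0, L=0)
    assert mae_loss(xp, xhat, plan, "all_patches") == pytest.approx(1.0)


@pytest.mark.parametrize("scope", ["masked_only", "all_patches"])
def test_mae_loss_matches_double_loop(scope, rng):
    N, E = 12, 9
    xp = rng.uniform(size=(N, E))
    xhat = rng.uniform(size=(N, E))
    plan = make_mask(N, 0.75, seed=1)
    total, count = 0.0, 0
    for p in range(N):
        if scope == "masked_only" and not plan.mask[p]:
            continue
        acc = 0.0
        for e in range(E):
            acc += (xp[p, e] - xhat[p, e]) ** 2
        total += acc / E
        count += 1
    assert mae_loss(xp, xhat, plan, scope) == pytest.approx(total / count, abs=1e-6)


def test_mae_loss_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        mae_loss(np.zeros((3, 4)), np.zeros((3, 5)), make_mask(3, 0.5, 0))


# ------------------------------------------------------------------ InfoNCE

def test_infonce_single_pair_is_zero(rng):
    z = rng.standard_normal((2, 6))
    assert info_nce_loss(z, make_synthetic_batch(2)) == pytest.approx(0.0, abs=1e-12)


def test_infonce_identical_projections_log3():
    z = np.ones((4, 5))
    cfg = LossConfig(lam=1.0, temperature=1.0, normalize_projections=False)
    assert info_nce_loss(z, make_synthetic_batch(4), cfg) == pytest.approx(np.log(3.0))


def test_infonce_matches_scalar_enumeration(rng):
    cfg = LossConfig(lam=1.0, temperature=1.0, normalize_projections=False)
    z = rng.standard_normal((8, 7))
    batch = make_synthetic_batch(8)
    expected = 0.0
    for i in batch.anchors:
        ip = batch.positive_of[i]
        num = np.exp(z[i] @ z[ip])
        den = sum(np.exp(z[i] @ z[j]) for j in range(8) if j != i)
        expected += -np.log(num / den)
    expected *= 2.0 / 8
    assert info_nce_loss(z, batch, cfg) == pytest.approx(expected, abs=1e-6)


def test_infonce_invariant_to_batch_relabeling(rng):
    cfg = LossConfig(temperature=0.5, normalize_projections=True)
    z = rng.standard_normal((8, 5))
    batch = make_synthetic_batch(8)
    perm = np.random.default_rng(1).permutation(8)
    inv = np.argsort(perm)
    z2 = z[perm]
    relabeled = ContrastiveBatch(
        frames=[batch.frames[p] for p in perm],
        anchors=[int(inv[i]) for i in batch.anchors],
        positive_of={int(inv[i]): int(inv[j]) for i, j in batch.positive_of.items()},
        provenance=[batch.provenance[p] for p in perm])
    assert info_nce_loss(z2, relabeled, cfg) == pytest.approx(
        info_nce_loss(z, batch, cfg), abs=1e-10)


def test_infonce_missing_positive_raises(rng):
    batch = make_synthetic_batch(4)
    del batch.positive_of[batch.anchors[0]]
    with pytest.raises(ValueError, match="no positive"):
        info_nce_loss(rng.standard_normal((4, 3)), batch)


# --------------------------------------------------------------- total loss

def test_total_loss_arithmetic():
    assert total_loss(0.5, 1.0, 0.1) == pytest.approx(0.6)
    assert total_loss(0.5, 1.0, 0.0) == pytest.approx(0.5)   # MAE-only variant
    assert total_loss(0.0, 2.0, 10.0) > total_loss(0.0, 2.0, 1.0)


# ---------------------------------------------------------------- train loop

@pytest.fixture(scope="module")
def loop_scene():
    return generate_scene(SceneConfig(image_height=32, image_width=32,
                                      sprite_radius=5.0, n_frames=150, seed=13))


def _loop_config():
    return EncoderConfig(image_size=32, P=8, D=32, depth=1, heads=2,
                         decoder_width=16, decoder_depth=1,
                         projector_hidden=32, projector_out=16, seed=0)


def test_zero_steps_returns_initial_weights(loop_scene):
    from beast.backbone import VisionTransformer
    init = VisionTransformer(_loop_config()).state_dict()
    res = pretrain([loop_scene.frames], _loop_config(), LossConfig(),
                   steps=0, batch_size=4, min_negative_gap=10, seed=0)
    out = res.model.state_dict()
    assert all(np.array_equal(init[k], out[k]) for k in init)


def test_same_seed_reproduces_loss_history(loop_scene):
    kw = dict(steps=5, batch_size=4, min_negative_gap=10, seed=3)
    a = pretrain([loop_scene.frames], _loop_config(), LossConfig(), **kw)
    b = pretrain([loop_scene.frames], _loop_config(), LossConfig(), **kw)
    assert a.history.equals(b.history)
    sa, sb = a.model.state_dict(), b.model.state_dict()
    assert all(np.array_equal(sa[k], sb[k]) for k in sa)


def test_projector_gets_no_gradient_without_contrastive_term(loop_scene):
    res = pretrain([loop_scene.frames], _loop_config(),
                   LossConfig(lam=0.0), steps=1, batch_size=4,
                   min_negative_gap=10, seed=0)
    for name, p in res.model.named_parameters():
        if name.startswith("projector"):
            assert p.grad is None or not p.grad.any()


def test_masked_pass_sharing_flag_runs(loop_scene):
    cfg = LossConfig(contrastive_full_pass=False)
    res = pretrain([loop_scene.frames], _loop_config(), cfg,
                   steps=3, batch_size=4, min_negative_gap=10, seed=0)
    assert np.isfinite(res.history.total).all()
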