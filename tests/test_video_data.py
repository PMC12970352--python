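"""Frame I/O, patch round trips, anchor selection and batch structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beast import (SceneConfig, generate_scene, write_scene, load_frames,
                   patchify, unpatchify, select_anchor_frames,
                   build_contrastive_batch, frames_from_array, CapacityError)
from beast.video_data import FrameRecord, PatchGrid


# ------------------------------------------------------------------- loading

def test_load_frames_round_trip(tmp_path):
    s = generate_scene(SceneConfig(n_frames=5, seed=1))
    write_scene(s, tmp_path / "scene")
    recs = load_frames(tmp_path / "scene" / "frames", [0, 3])
    assert [r.t for r in recs] == [0, 3]
    assert np.abs(recs[0].image - s.frames[0]).max() <= 1.0 / 255.0
    again = load_frames(tmp_path / "scene" / "frames", [0])
    assert np.array_equal(recs[0].image, again[0].image)


def test_load_frames_out_of_range_names_index(tmp_path):
    s = generate_scene(SceneConfig(n_frames=3, seed=1))
    write_scene(s, tmp_path / "scene")
    with pytest.raises(LookupError, match="7"):
        load_frames(tmp_path / "scene" / "frames", [7])


# ------------------------------------------------------------------ patchify

def test_patchify_canonical_vit_geometry(rng):
    img = rng.uniform(size=(224, 224, 3))
    grid = patchify(img, 16)
    assert grid.patches.shape == (196, 768)     # N = (224/16)^2, P^2*C


def test_patchify_constant_image():
    img = np.full((32, 32, 3), 0.25)
    grid = patchify(img, 8)
    assert np.all(grid.patches == 0.25)


def test_patchify_unpatchify_inverse(rng):
    img = rng.uniform(size=(32, 32, 3))
    assert np.array_equal(unpatchify(patchify(img, 8)), img)


def test_patchify_row_major_layout():
    # patch p must be the row-major flattening, patches in row-major grid order
    img = np.arange(4 * 4 * 1, dtype=float).reshape(4, 4, 1)
    img = np.repeat(img, 3, axis=2)
    grid = patchify(img, 2)
    assert np.array_equal(grid.patches[0].reshape(2, 2, 3), img[:2, :2])
    assert np.array_equal(grid.patches[1].reshape(2, 2, 3), img[:2, 2:])


def test_patchify_indivisible_raises():
    with pytest.raises(ValueError, match="not divisible"):
        patchify(np.zeros((30, 32, 3)), 8)


def test_unpatchify_inconsistent_grid_raises():
    with pytest.raises(ValueError, match="inconsistent"):
        unpatchify(PatchGrid(patches=np.zeros((5, 12)), grid_h=2, grid_w=2, P=2))


# ----------------------------------------------------------- anchor selection

def _records(images):
    return [FrameRecord("v", t, img) for t, img in enumerate(images)]


def test_anchor_selection_on_identical_frames_is_deterministic():
    frames = _records([np.full((8, 8, 3), 0.5)] * 6)
    a = select_anchor_frames(frames, 3, seed=11)
    b = select_anchor_frames(frames, 3, seed=11)
    assert a == b and len(set(a)) == 3


def test_anchor_selection_splits_appearance_clusters():
    # brute force over all pairs: max pairwise distance pairs one black
    # with one white frame — greedy selection must do the same
    images = [np.zeros((8, 8, 3))] * 5 + [np.ones((8, 8, 3))] * 5
    frames = _records(images)
    for seed in range(5):
        sel = select_anchor_frames(frames, 2, seed=seed)
        assert (sel[0] < 5) != (sel[1] < 5)


def test_anchor_selection_exhaustive():
    frames = _records([np.full((8, 8, 3), v / 10) for v in range(4)])
    assert sorted(select_anchor_frames(frames, 4, seed=0)) == [0, 1, 2, 3]


def test_anchor_selection_capacity():
    with pytest.raises(CapacityError):
        select_anchor_frames(_records([np.zeros((8, 8, 3))] * 3), 5, seed=0)


# ------------------------------------------------------------------- batches

def _video(n, seed, size=16):
    rng = np.random.default_rng(seed)
    return frames_from_array(rng.uniform(size=(n, size, size, 3)), f"vid{seed}")


def test_batch_structure_b16():
    batch = build_contrastive_batch([_video(200, 0), _video(200, 1)], 16,
                                    min_negative_gap=30, seed=0)
    assert len(batch.anchors) == 8
    assert len(batch.positive_of) == 8
    for i in batch.anchors:
        fi, fp = batch.frames[i], batch.frames[batch.positive_of[i]]
        assert fi.video_id == fp.video_id and abs(fi.t - fp.t) == 1
        # every other frame in the batch acts as a negative for this anchor
        negatives = [j for j in range(16) if j != i and j != batch.positive_of[i]]
        assert len(negatives) == 14


def test_anchor_at_sequence_boundary_uses_only_valid_neighbor():
    # 2-frame video: whichever frame is the anchor, the other is the positive
    for seed in range(6):
        batch = build_contrastive_batch([_video(2, seed)], 2,
                                        min_negative_gap=0, seed=seed)
        ts = sorted(f.t for f in batch.frames)
        assert ts == [0, 1]


def test_infeasible_batch_names_constraint():
    with pytest.raises(CapacityError, match="min_negative_gap"):
        build_contrastive_batch([_video(5, 0)], 8, min_negative_gap=30, seed=0)


def test_batch_is_deterministic_given_seed():
    vids = [_video(120, 3)]
    a = build_contrastive_batch(vids, 8, min_negative_gap=10, seed=42)
    b = build_contrastive_batch(vids, 8, min_negative_gap=10, seed=42)
    assert a.provenance == b.provenance and a.anchors == b.anchors


def test_augment_pair_applies_identical_transform(rng):
    """Flip and photometric jitter are shared within a pair (seeded oracle)."""
    from beast.video_data import augment_pair
    a = rng.uniform(0.2, 0.8, size=(8, 8, 3))
    b = rng.uniform(0.2, 0.8, size=(8, 8, 3))
    for s in range(5):
        aa, bb = augment_pair(a, b, np.random.default_rng(s))
        # oracle: replay the same generator draws
        oracle_rng = np.random.default_rng(s)
        ra, rb = (a, b) if oracle_rng.uniform() >= 0.5 else (a[:, ::-1], b[:, ::-1])
        br = oracle_rng.uniform(-0.1, 0.1)
        ct = 1.0 + oracle_rng.uniform(-0.1, 0.1)
        exp_a = np.clip((ra - ra.mean()) * ct + ra.mean() + br, 0, 1)
        exp_b = np.clip((rb - rb.mean()) * ct + rb.mean() + br, 0, 1)
        assert np.allclose(aa, exp_a) and np.allclose(bb, exp_b)
        assert 0.0 <= aa.min() and aa.max() <= 1.0


def test_pretrain_with_augmentation_runs(tiny_scene):
    from beast import pretrain
    from beast.backbone import EncoderConfig
    from beast.pretraining import LossConfig
    enc = EncoderConfig(image_size=32, P=8, D=32, depth=1, heads=2,
                        decoder_width=16, decoder_depth=1,
                        projector_hidden=32, projector_out=16, seed=0)
    res = pretrain([tiny_scene.frames], enc, LossConfig(), steps=3,
                   batch_size=4, min_negative_gap=10, seed=0, augment=True)
    assert np.isfinite(res.history.total).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_videos=st.integers(1, 3),
    length=st.integers(60, 150),
    b_half=st.sampled_from([2, 4]),
    gap=st.sampled_from([5, 15, 30]),
    seed=st.integers(0, 10_000),
)
def test_every_emitted_batch_satisfies_invariants(n_videos, length, b_half, gap, seed):
    videos = [_video(length, v + 100, size=8) for v in range(n_videos)]
    B = 2 * b_half
    try:
        batch = build_contrastive_batch(videos, B, min_negative_gap=gap, seed=seed)
    except CapacityError:
        return
    batch.validate(min_negative_gap=gap)   # raises on violation
    assert len(batch.frames) == B
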