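"""Frame I/O, patch tokenization inputs, and contrastive batch construction.

The contrastive sampling scheme is the heart of the temporal objective:
each batch of B frames contains B/2 *anchor* frames chosen to be visually
distinct from each other, each anchor is paired with a *positive* frame
drawn from its immediate temporal neighbors (t-1 or t+1), and every other
frame in the batch acts as a negative.  Same-video negatives are kept
temporally distant from every anchor (``min_negative_gap``), so negatives
are genuinely dissimilar behavior, not near-duplicates of the positive.
"""

from __future__ import annotations

import dataclasses
import pathlib
import re

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import zoom as _zoom

__all__ = [
    "FrameRecord", "PatchGrid", "ContrastiveBatch", "CapacityError",
    "load_frames", "patchify", "unpatchify",
    "select_anchor_frames", "build_contrastive_batch", "frames_from_array",
    "augment_pair",
]


class CapacityError(ValueError):
    """Raised when a batch request cannot be satisfied by the available frames."""


@dataclasses.dataclass
class FrameRecord:
    """One video frame: ``image`` is (H, W, 3) float in [0, 1]."""

    video_id: str
    t: int
    image: np.ndarray


@dataclasses.dataclass
class PatchGrid:
    """Flattened non-overlapping patches of one frame.

    ``patches`` has shape (N, P*P*C); row p is the row-major flattening of
    patch p, patches read in row-major grid order.
    """

    patches: np.ndarray
    grid_h: int
    grid_w: int
    P: int


@dataclasses.dataclass
class ContrastiveBatch:
    frames: list            # B FrameRecords
    anchors: list           # indices of the B/2 anchor frames
    positive_of: dict       # anchor index -> positive index
    provenance: list        # (video_id, t) per frame

    def validate(self, min_negative_gap: int = 0):
        B = len(self.frames)
        if B % 2 != 0:
            raise ValueError(f"batch size must be even, got {B}")
        pos = set(self.positive_of.values())
        anc = set(self.anchors)
        if len(anc) != B // 2 or len(pos) != B // 2 or (anc | pos) != set(range(B)):
            raise ValueError("anchors and positives must partition the batch")
        for i in self.anchors:
            j = self.positive_of[i]
            fi, fj = self.frames[i], self.frames[j]
            if fi.video_id != fj.video_id or abs(fi.t - fj.t) != 1:
                raise ValueError(
                    f"positive of anchor {i} must be an adjacent frame of the same video"
                )
        paired = {(i, self.positive_of[i]) for i in self.anchors}
        paired |= {(j, i) for i, j in paired}
        for a in range(B):
            for b in range(a + 1, B):
                if (a, b) in paired:
                    continue
                fa, fb = self.frames[a], self.frames[b]
                if fa.video_id == fb.video_id and abs(fa.t - fb.t) < min_negative_gap:
                    raise ValueError(
                        f"same-video non-positive frames {a},{b} are only "
                        f"{abs(fa.t - fb.t)} frames apart (gap {min_negative_gap})"
                    )


_FRAME_FILE = re.compile(r".*?(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


def _list_frame_files(directory: pathlib.Path) -> list:
    files = []
    for f in sorted(directory.iterdir()):
        m = _FRAME_FILE.match(f.name)
        if m:
            files.append((int(m.group(1)), f))
    files.sort(key=lambda x: x[0])
    return [f for _, f in files]


def _resize_center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Shorter-side resize to ``size`` then center crop to (size, size)."""
    H, W = img.shape[:2]
    scale = size / min(H, W)
    if scale != 1.0:
        img = _zoom(img, (scale, scale, 1), order=1)
    H, W = img.shape[:2]
    top = (H - size) // 2
    left = (W - size) // 2
    return np.clip(img[top:top + size, left:left + size], 0.0, 1.0)


def load_frames(source, indices, size: int | None = None) -> list:
    """Load frames from a frame directory or a video container.

    Frames come back as :class:`FrameRecord` with RGB float images in
    [0, 1], optionally shorter-side resized and center-cropped to
    ``size`` x ``size``.
    """
    src = pathlib.Path(source)
    records = []
    if src.is_dir():
        files = _list_frame_files(src)
        n = len(files)
        for t in indices:
            if t < 0 or t >= n:
                raise LookupError(f"frame index {t} out of range for {n}-frame source {src}")
            try:
                img = np.asarray(iio.imread(files[t]), dtype=np.float64) / 255.0
            except Exception as exc:
                raise ValueError(f"cannot decode frame file {files[t]}: {exc}") from exc
            records.append(FrameRecord(video_id=str(src), t=int(t), image=img))
    else:
        try:
            video = np.asarray(iio.imread(src), dtype=np.float64) / 255.0
        except Exception as exc:
            raise ValueError(f"cannot decode video container {src}: {exc}") from exc
        for t in indices:
            if t < 0 or t >= video.shape[0]:
                raise LookupError(
                    f"frame index {t} out of range for {video.shape[0]}-frame source {src}")
            records.append(FrameRecord(video_id=str(src), t=int(t), image=video[t]))
    for r in records:
        if r.image.ndim == 2:
            r.image = np.repeat(r.image[..., None], 3, axis=-1)
        if r.image.shape[-1] == 4:
            r.image = r.image[..., :3]
        if size is not None:
            r.image = _resize_center_crop(r.image, size)
    return records


def frames_from_array(frames: np.ndarray, video_id: str) -> list:
    """Wrap an in-memory (T, H, W, 3) array as a list of FrameRecords."""
    return [FrameRecord(video_id=video_id, t=t, image=np.asarray(frames[t], dtype=np.float64))
            for t in range(frames.shape[0])]


def patchify(frame, P: int) -> PatchGrid:
    """Split a frame into non-overlapping P x P x C patches."""
    img = frame.image if isinstance(frame, FrameRecord) else np.asarray(frame)
    H, W, C = img.shape
    if H % P != 0 or W % P != 0:
        raise ValueError(f"image size ({H}, {W}) not divisible by patch size P={P}")
    gh, gw = H // P, W // P
    patches = (img.reshape(gh, P, gw, P, C)
                  .transpose(0, 2, 1, 3, 4)
                  .reshape(gh * gw, P * P * C))
    return PatchGrid(patches=patches, grid_h=gh, grid_w=gw, P=P)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    N = grid.patches.shape[0]
    if N != grid.grid_h * grid.grid_w:
        raise ValueError(
            f"patch count {N} inconsistent with grid {grid.grid_h}x{grid.grid_w}")
    C = grid.patches.shape[1] // (grid.P * grid.P)
    gh, gw, P = grid.grid_h, grid.grid_w, grid.P
    return (grid.patches.reshape(gh, gw, P, P, C)
                 .transpose(0, 2, 1, 3, 4)
                 .reshape(gh * P, gw * P, C))


def _thumbnail(image: np.ndarray, size: int = 32) -> np.ndarray:
    gray = image.mean(axis=-1)
    H, W = gray.shape
    return _zoom(gray, (size / H, size / W), order=1).ravel()


def select_anchor_frames(video_frames, k: int, seed: int,
                         thumbnails: np.ndarray | None = None) -> list:
    """Greedy farthest-point selection of visually distinct anchor frames.

    The first anchor is drawn uniformly (seeded); each subsequent anchor
    maximizes the minimum L2 distance, on 32x32 grayscale downsamples, to
    the anchors already selected.  Ties break toward the lowest frame
    index, so the result is deterministic given the seed.
    """
    n = len(video_frames)
    if k > n:
        raise CapacityError(f"requested {k} anchors from only {n} candidate frames")
    if thumbnails is None:
        thumbnails = np.stack([_thumbnail(f.image) for f in video_frames])
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    selected = [first]
    min_dist = np.linalg.norm(thumbnails - thumbnails[first], axis=1)
    while len(selected) < k:
        min_dist[selected] = -1.0
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        d = np.linalg.norm(thumbnails - thumbnails[nxt], axis=1)
        min_dist = np.minimum(min_dist, d)
    return selected


def _constrained_anchor_selection(video_frames, k, min_sep, rng, thumbnails):
    """Farthest-point selection with a minimum temporal separation.

    If appearance-greedy selection paints itself into a corner, fall back
    to an evenly spaced temporal grid (always feasible when capacity is).
    """
    n = len(video_frames)
    times = np.array([f.t for f in video_frames])
    alive = np.ones(n, dtype=bool)
    first = int(rng.integers(n))
    selected = [first]
    alive[np.abs(times - times[first]) < min_sep] = False
    min_dist = np.linalg.norm(thumbnails - thumbnails[first], axis=1)
    while len(selected) < k:
        if not alive.any():
            # appearance-greedy got stuck; evenly spaced temporal fallback
            step = min_sep
            fallback = list(range(0, n, step))[:k]
            if len(fallback) < k:
                raise CapacityError(
                    f"cannot place {k} anchors with separation {min_sep} in "
                    f"{n} frames")
            return fallback
        masked = np.where(alive, min_dist, -1.0)
        nxt = int(np.argmax(masked))
        selected.append(nxt)
        alive[np.abs(times - times[nxt]) < min_sep] = False
        min_dist = np.minimum(min_dist, np.linalg.norm(thumbnails - thumbnails[nxt], axis=1))
    return selected


def build_contrastive_batch(videos, B: int, min_negative_gap: int = 30,
                            seed: int = 0, thumbnails=None) -> ContrastiveBatch:
    """Assemble a contrastive batch from one or more frame sequences.

    ``videos`` is a list of frame sequences (lists of FrameRecord).
    B/2 anchors are spread across videos round-robin; each positive is the
    anchor's t-1 or t+1 frame (uniform, clipped at clip boundaries).
    Same-video anchors are kept ``min_negative_gap + 2`` frames apart so
    that no same-video non-positive pair is closer than the gap.
    """
    if B % 2 != 0:
        raise ValueError(f"batch size must be even, got {B}")
    n_anchors = B // 2
    rng = np.random.default_rng(seed)
    min_sep = min_negative_gap + 2

    # per-video anchor capacity under the separation constraint
    caps = []
    for v, frames in enumerate(videos):
        n = len(frames)
        if n < 2:
            caps.append(0)
            continue
        caps.append((n - 1) // min_sep + 1)
    if sum(caps) < n_anchors:
        raise CapacityError(
            f"need {n_anchors} anchors but videos support only {sum(caps)} under "
            f"min_negative_gap={min_negative_gap} "
            f"(video lengths {[len(v) for v in videos]})")

    # round-robin quota assignment
    quota = [0] * len(videos)
    v = 0
    assigned = 0
    while assigned < n_anchors:
        if quota[v] < caps[v]:
            quota[v] += 1
            assigned += 1
        v = (v + 1) % len(videos)

    if thumbnails is None:
        thumbnails = [np.stack([_thumbnail(f.image) for f in frames]) if len(frames) else None
                      for frames in videos]

    batch_frames, anchors, positive_of, provenance = [], [], {}, []
    for v, frames in enumerate(videos):
        if quota[v] == 0:
            continue
        idx = _constrained_anchor_selection(frames, quota[v], min_sep, rng, thumbnails[v])
        n = len(frames)
        for i in idx:
            t = frames[i].t
            # positive from {t-1, t+1}, clipped at sequence boundaries
            choices = [j for j in (i - 1, i + 1) if 0 <= j < n]
            j = choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices[0]
            a_pos = len(batch_frames)
            batch_frames.append(frames[i])
            provenance.append((frames[i].video_id, frames[i].t))
            batch_frames.append(frames[j])
            provenance.append((frames[j].video_id, frames[j].t))
            anchors.append(a_pos)
            positive_of[a_pos] = a_pos + 1
            assert abs(frames[j].t - t) == 1

    batch = ContrastiveBatch(frames=batch_frames, anchors=anchors,
                             positive_of=positive_of, provenance=provenance)
    batch.validate(min_negative_gap=min_negative_gap)
    return batch


def augment_pair(anchor_img: np.ndarray, positive_img: np.ndarray,
                 rng: np.random.Generator, p_hflip: float = 0.5,
                 brightness: float = 0.1, contrast: float = 0.1):
    """Photometric/geometric augmentation applied identically to both frames.

    A horizontal flip (probability ``p_hflip``) plus mild brightness and
    contrast jitter.  Anchor and positive always receive the same
    transform, so the augmentation never changes which pair is positive.
    Off by default in the training loop.
    """
    a, p = anchor_img, positive_img
    if rng.uniform() < p_hflip:
        a, p = a[:, ::-1], p[:, ::-1]
    b = rng.uniform(-brightness, brightness)
    c = 1.0 + rng.uniform(-contrast, contrast)
    out = []
    for img in (a, p):
        mean = img.mean()
        out.append(np.clip((img - mean) * c + mean + b, 0.0, 1.0))
    return out[0], out[1]
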