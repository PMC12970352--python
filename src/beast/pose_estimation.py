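"""Heatmap-based pose estimation on transformer patch embeddings.

A simple two-stage upsampling head (each stage doubles the patch grid via a
learned pixel-shuffle expansion, i.e. a kernel-2/stride-2 transposed
convolution) maps patch embeddings to K keypoint heatmaps at 4x the patch
grid resolution.  Targets are unit-peak Gaussians; decoding is a softmax
soft-argmax, so predictions are sub-pixel and differentiable.  Evaluation
follows the pixel-error-versus-ensemble-s.d. protocol: keypoints are ranked
by the spread of an ensemble's predictions and error is reported over
increasingly difficult subsets.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import VisionTransformer

__all__ = ["KeypointLabels", "PoseEval", "PoseHead", "PoseModel",
           "make_target_heatmaps", "decode_keypoints", "pose_head_forward",
           "train_pose", "pixel_error", "esd_curve"]

SOFTARGMAX_BETA = 20.0   # softmax sharpness; calibrated to the sigma=2 target codec


@dataclasses.dataclass
class KeypointLabels:
    """Labeled frames: keypoints (F, K, 2) pixel (x, y), visibility (F, K)."""

    keypoints: np.ndarray
    visibility: np.ndarray | None = None

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.visibility is None:
            self.visibility = np.ones(self.keypoints.shape[:2], dtype=bool)
        self.visibility = np.asarray(self.visibility, dtype=bool)


@dataclasses.dataclass
class PoseEval:
    thresholds: np.ndarray
    errors: np.ndarray          # mean pixel error over keypoints with esd > tau
    subset_fraction: np.ndarray
    esd: np.ndarray             # (F, K)
    per_keypoint_error: np.ndarray  # (F, K), averaged over ensemble members


class PoseHead(nn.Module):
    """Two pixel-shuffle upsampling stages plus a pointwise convolution."""

    def __init__(self, D: int, K: int, grid_h: int, grid_w: int,
                 hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grid_h, self.grid_w, self.K = grid_h, grid_w, K
        self.up1 = nn.Linear(D, hidden * 4, rng)
        self.up2 = nn.Linear(hidden, hidden * 4, rng)
        self.out = nn.Linear(hidden, K, rng)
        self.hidden = hidden

    @staticmethod
    def _shuffle(x: Tensor, c: int) -> Tensor:
        """(B, h, w, 4c) -> (B, 2h, 2w, c) pixel shuffle."""
        B, h, w, _ = x.shape
        return (x.reshape(B, h, w, 2, 2, c)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(B, 2 * h, 2 * w, c))

    def forward(self, patch_embeddings: Tensor) -> Tensor:
        """(B, N, D) patch embeddings -> (B, 4*gh, 4*gw, K) heatmaps."""
        B, N, D = patch_embeddings.shape
        if N != self.grid_h * self.grid_w:
            raise ValueError(f"N={N} does not match grid {self.grid_h}x{self.grid_w}")
        x = patch_embeddings.reshape(B, self.grid_h, self.grid_w, D)
        x = self._shuffle(self.up1(x), self.hidden).gelu()
        x = self._shuffle(self.up2(x), self.hidden).gelu()
        return self.out(x)


def pose_head_forward(head: PoseHead, patch_embeddings) -> np.ndarray:
    """Inference-mode heatmaps for (B, N, D) embeddings."""
    x = patch_embeddings if isinstance(patch_embeddings, Tensor) else Tensor(patch_embeddings)
    with nn.no_grad():
        return head(x).numpy()


def make_target_heatmaps(keypoints: np.ndarray, map_h: int, map_w: int,
                         stride: float, sigma: float = 2.0) -> np.ndarray:
    """Unit-peak Gaussian targets at heatmap resolution.

    ``keypoints``: (F, K, 2) image-pixel (x, y); heatmap cell (i, j) maps to
    image pixel (j * stride, i * stride).
    """
    kp = np.asarray(keypoints, dtype=float) / stride
    F, K, _ = kp.shape
    ys, xs = np.meshgrid(np.arange(map_h, dtype=float),
                         np.arange(map_w, dtype=float), indexing="ij")
    maps = np.empty((F, map_h, map_w, K))
    for k in range(K):
        d2 = ((xs[None] - kp[:, k, 0, None, None]) ** 2
              + (ys[None] - kp[:, k, 1, None, None]) ** 2)
        maps[..., k] = np.exp(-d2 / (2.0 * sigma ** 2))
    return maps


def decode_keypoints(maps: np.ndarray, stride: float = 1.0, beta: float = SOFTARGMAX_BETA):
    """Soft-argmax decoding after softmax normalization.

    ``maps``: (F, H', W', K).  Returns image-pixel keypoints (F, K, 2) and
    confidences (F, K) — the max of each softmax-normalized map.  Two equal
    peaks decode to their midpoint (soft-argmax contract).
    """
    m = np.asarray(maps, dtype=float)
    if np.isnan(m).any():
        raise FloatingPointError("heatmaps contain NaN values")
    F, H, W, K = m.shape
    flat = (beta * m).reshape(F, H * W, K)
    flat = flat - flat.max(axis=1, keepdims=True)
    w = np.exp(flat)
    w /= w.sum(axis=1, keepdims=True)
    ys, xs = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    x = (w * xs.reshape(1, -1, 1)).sum(axis=1)
    y = (w * ys.reshape(1, -1, 1)).sum(axis=1)
    conf = w.max(axis=1)
    return np.stack([x, y], axis=-1) * stride, conf


class PoseModel(nn.Module):
    """Backbone + heatmap head; trained end-to-end."""

    def __init__(self, backbone: VisionTransformer, K: int, hidden: int = 64,
                 seed: int = 0, sigma: float = 2.0):
        cfg = backbone.config
        g = cfg.image_size // cfg.P
        self.backbone = backbone
        self.head = PoseHead(cfg.D, K, g, g, hidden=hidden, seed=seed)
        self.sigma = sigma
        self.stride = cfg.P / 4.0       # head upsamples the patch grid 4x
        self.map_size = g * 4

    def heatmaps(self, images: np.ndarray, grad: bool = False) -> Tensor:
        emb = self.backbone.embed_frames(images, grad=grad)
        if grad:
            return self.head(emb.patch_embeddings)
        with nn.no_grad():
            return self.head(emb.patch_embeddings)

    def predict(self, images: np.ndarray, batch_size: int = 32):
        kps, confs = [], []
        for s in range(0, images.shape[0], batch_size):
            maps = self.heatmaps(np.asarray(images[s:s + batch_size], dtype=np.float64))
            kp, cf = decode_keypoints(maps.numpy(), stride=self.stride)
            kps.append(kp)
            confs.append(cf)
        return np.concatenate(kps), np.concatenate(confs)


def train_pose(frames: np.ndarray, labels: KeypointLabels,
               backbone: VisionTransformer | str, *, seed: int = 0,
               epochs: int = 30, batch_size: int = 10, lr: float = 1e-3,
               hidden: int = 64, sigma: float = 2.0,
               weight_decay: float = 1e-4) -> PoseModel:
    """Fine-tune backbone + heatmap head on labeled frames (visibility-masked MSE)."""
    if labels.keypoints.shape[0] == 0:
        raise ValueError("empty label set")
    if not isinstance(backbone, VisionTransformer):
        backbone = VisionTransformer.load_checkpoint(backbone)
    K = labels.keypoints.shape[1]
    model = PoseModel(backbone, K, hidden=hidden, seed=seed, sigma=sigma)
    targets = make_target_heatmaps(labels.keypoints, model.map_size, model.map_size,
                                   model.stride, sigma=sigma)
    vis = labels.visibility.astype(float)          # (F, K)
    F = frames.shape[0]
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    n_steps = epochs * int(np.ceil(F / batch_size))
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(F)
        for s in range(0, F, batch_size):
            sel = order[s:s + batch_size]
            maps = model.heatmaps(np.asarray(frames[sel], dtype=np.float64), grad=True)
            diff = maps - Tensor(targets[sel])
            per_kp = (diff * diff).mean(axis=1).mean(axis=1)     # (b, K)
            w = vis[sel]
            loss = (per_kp * Tensor(w)).sum() / max(w.sum(), 1.0)
            model.zero_grad()
            loss.backward()
            opt.lr = nn.cosine_lr(step, n_steps, lr)
            opt.step()
            step += 1
    return model


def pixel_error(pred: np.ndarray, truth: np.ndarray, visibility=None):
    """Euclidean error per keypoint; returns (per-keypoint array, visible mean)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"keypoint shape mismatch {pred.shape} vs {truth.shape}")
    err = np.linalg.norm(pred - truth, axis=-1)
    if visibility is None:
        return err, float(err.mean())
    visibility = np.asarray(visibility, dtype=bool)
    return err, float(err[visibility].mean())


def esd_curve(ensemble_preds: np.ndarray, truth: np.ndarray,
              thresholds=None) -> PoseEval:
    """Pixel error as a function of ensemble disagreement.

    ``ensemble_preds``: (M, F, K, 2) keypoints from M models.  The e.s.d. of
    a (frame, keypoint) is the root mean squared Euclidean deviation of the
    members from their ensemble mean.  Each curve point is the mean pixel
    error (averaged over members) over keypoints whose e.s.d. exceeds the
    threshold; the tau = 0 point covers all keypoints.
    """
    preds = np.asarray(ensemble_preds, dtype=float)
    if preds.ndim != 4 or preds.shape[0] < 2:
        raise ValueError("need an (M, F, K, 2) ensemble with M >= 2")
    truth = np.asarray(truth, dtype=float)
    mean_pred = preds.mean(axis=0)
    esd = np.sqrt(((preds - mean_pred) ** 2).sum(axis=-1).mean(axis=0))   # (F, K)
    err = np.linalg.norm(preds - truth, axis=-1).mean(axis=0)             # (F, K)
    if thresholds is None:
        hi = float(esd.max())
        thresholds = np.concatenate([[0.0], np.linspace(0.0, hi, 6)[1:]]) if hi > 0 \
            else np.array([0.0])
    thresholds = np.asarray(thresholds, dtype=float)
    errors, fracs = [], []
    for tau in thresholds:
        sel = esd > tau if tau > 0 else np.ones_like(esd, dtype=bool)
        fracs.append(sel.mean())
        errors.append(float(err[sel].mean()) if sel.any() else np.nan)
    return PoseEval(thresholds=thresholds, errors=np.asarray(errors),
                    subset_fraction=np.asarray(fracs), esd=esd,
                    per_keypoint_error=err)
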