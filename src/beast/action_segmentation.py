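"""Frozen-backbone action segmentation.

Frame-level features (CLS embeddings, or patch embeddings integrated by
multi-head attention pooling) are enriched with inter-frame differences and
classified frame-by-frame with a sliding-window head — linear or a small
temporal convolution network predicting the class of the central frame.
Multiple seeds are ensembled by averaging logits *before* the softmax, and
performance is scored with the macro-averaged F1, optionally over a named
class subset.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "Ethogram", "WindowedFeatures", "LogitsSeries", "AttentionPool",
    "attention_pool", "pool_video_features", "build_windows",
    "train_segmenter", "ensemble_predict", "macro_f1", "SegmenterModel",
]


@dataclasses.dataclass
class Ethogram:
    labels: np.ndarray
    class_names: list | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.class_names is None:
            self.class_names = [str(c) for c in range(int(self.labels.max()) + 1)]
        if (self.labels < 0).any() or (self.labels >= len(self.class_names)).any():
            raise ValueError("labels out of range for the class map")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclasses.dataclass
class WindowedFeatures:
    """Per frame: a centered window of [feature ; inter-frame difference] rows.

    ``windows`` has shape (T, W, 2d): the difference channel at t is
    f_t - f_{t-1} (zero row at t = 0) and sequence edges are padded by
    replication.
    """

    windows: np.ndarray
    W: int

    @property
    def central(self) -> np.ndarray:
        return self.windows[:, self.W // 2, :]


@dataclasses.dataclass
class LogitsSeries:
    per_model: np.ndarray     # (M, T, K)
    ensemble_probs: np.ndarray  # (T, K), softmax of the mean logits


class AttentionPool(nn.Module):
    """Single learned query attending over patch embeddings (multi-head).

    The pooling operator adds no positional information of its own — patch
    embeddings already carry position.  Initialization is seeded; the pool
    is used as a fixed frame-feature extractor over a frozen backbone.
    """

    def __init__(self, D: int, heads: int = 4, seed: int = 0):
        if D % heads != 0:
            raise ValueError(f"feature width {D} not divisible by {heads} heads")
        rng = np.random.default_rng(seed)
        self.heads = heads
        self.head_dim = D // heads
        self.query = Tensor(nn.trunc_normal(rng, (1, D), std=1.0), requires_grad=True)
        self.key = nn.Linear(D, D, rng, std=1.0 / np.sqrt(D))
        self.value = nn.Linear(D, D, rng, std=1.0 / np.sqrt(D))
        self.out = nn.Linear(D, D, rng, std=1.0 / np.sqrt(D))

    def forward(self, patch_embeddings: Tensor) -> Tensor:
        """(B, N, D) -> (B, D) pooled frame vectors."""
        x = patch_embeddings
        B, N, D = x.shape
        h, hd = self.heads, self.head_dim
        k = self.key(x).reshape(B, N, h, hd).transpose(0, 2, 1, 3)    # (B,h,N,hd)
        v = self.value(x).reshape(B, N, h, hd).transpose(0, 2, 1, 3)
        q = self.query.reshape(1, 1, h, hd).transpose(0, 2, 1, 3)     # (1,h,1,hd)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))     # (B,h,1,N)
        att = att.softmax(axis=-1)
        pooled = (att @ v).transpose(0, 2, 1, 3).reshape(B, D)
        return self.out(pooled)


def attention_pool(patch_embeddings, heads: int = 4, seed: int = 0,
                   pool: AttentionPool | None = None) -> np.ndarray:
    """Pool (B, N, D) patch embeddings to (B, D) frame vectors."""
    x = patch_embeddings if isinstance(patch_embeddings, Tensor) else Tensor(np.asarray(patch_embeddings))
    if pool is None:
        pool = AttentionPool(x.shape[-1], heads=heads, seed=seed)
    with nn.no_grad():
        return pool(x).numpy()


def pool_video_features(frames: np.ndarray, backbone, *, source: str = "patch",
                        heads: int = 4, seed: int = 0, batch_size: int = 64) -> np.ndarray:
    """Frozen-backbone frame features for a whole video.

    ``source='patch'`` attention-pools patch embeddings; ``source='cls'``
    returns CLS embeddings.
    """
    from .backbone import VisionTransformer
    if not isinstance(backbone, VisionTransformer):
        backbone = VisionTransformer.load_checkpoint(backbone)
    pool = AttentionPool(backbone.config.D, heads=heads, seed=seed) if source == "patch" else None
    rows = []
    for s in range(0, frames.shape[0], batch_size):
        emb = backbone.embed_frames(np.asarray(frames[s:s + batch_size], dtype=np.float64))
        if source == "cls":
            rows.append(emb.cls_embedding.numpy())
        elif source == "patch":
            rows.append(attention_pool(emb.patch_embeddings, pool=pool))
        else:
            raise ValueError(f"unknown feature source {source!r}")
    return np.concatenate(rows, axis=0)


def build_windows(features: np.ndarray, W: int) -> WindowedFeatures:
    """Centered sliding windows of [feature ; difference], replication-padded."""
    f = np.asarray(features, dtype=float)
    if f.ndim == 1:
        f = f[:, None]
    T = f.shape[0]
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window W must be odd and positive, got {W}")
    if W > 2 * T - 1:
        raise ValueError(f"window W={W} too large for {T} frames")
    diff = np.zeros_like(f)
    diff[1:] = f[1:] - f[:-1]
    enriched = np.concatenate([f, diff], axis=1)        # (T, 2d)
    half = W // 2
    idx = np.clip(np.arange(T)[:, None] + np.arange(-half, half + 1)[None, :], 0, T - 1)
    return WindowedFeatures(windows=enriched[idx], W=W)


class SegmenterModel(nn.Module):
    """Sliding-window classifier head (linear, or a 2-layer TCN)."""

    def __init__(self, d_in: int, K: int, head: str = "tcn", W: int = 11,
                 hidden: int = 32, seed: int = 0):
        if head not in ("linear", "tcn"):
            raise ValueError(f"unknown head {head!r}")
        rng = np.random.default_rng(seed)
        self.head_kind = head
        self.W = W if head == "tcn" else 1
        self.K = K
        if head == "linear":
            self.fc = nn.Linear(d_in, K, rng)
        else:
            k1 = W // 2 + 1 if (W // 2) % 2 == 0 else W // 2 + 2
            k2 = W - k1 + 1
            self.conv1 = nn.Conv1d(d_in, hidden, k1, rng)
            self.conv2 = nn.Conv1d(hidden, hidden, k2, rng)
            self.fc = nn.Linear(hidden, K, rng)
        self.x_mean = np.zeros(d_in)
        self.x_std = np.ones(d_in)

    def _forward(self, seq: Tensor) -> Tensor:
        if self.head_kind == "linear":
            return self.fc(seq)
        h = self.conv1(seq).gelu()
        h = self.conv2(h).gelu()
        return self.fc(h)

    def logits(self, features) -> np.ndarray:
        seq = features.central if isinstance(features, WindowedFeatures) else np.asarray(features, dtype=float)
        with nn.no_grad():
            return self._forward(Tensor((seq - self.x_mean) / self.x_std)).numpy()

    def predict(self, features) -> np.ndarray:
        return self.logits(features).argmax(axis=1)


def train_segmenter(features, ethogram, head: str = "tcn", *, W: int = 11,
                    hidden: int = 32, seed: int = 0, epochs: int = 150,
                    lr: float = 5e-3, weight_decay: float = 1e-4,
                    class_weights: bool = False) -> SegmenterModel:
    """Cross-entropy training of the classification head only.

    ``features`` may be a WindowedFeatures (its central [feature ; diff]
    sequence is used — the TCN re-expands the temporal window internally,
    with the same replication padding) or a raw (T, d) array (then enriched
    and windowed with ``W``).  The backbone stays frozen by construction:
    only head parameters exist here.
    """
    if not isinstance(features, WindowedFeatures):
        features = build_windows(np.asarray(features), W)
    labels = ethogram.labels if isinstance(ethogram, Ethogram) else np.asarray(ethogram, dtype=np.int64)
    K = (ethogram.n_classes if isinstance(ethogram, Ethogram)
         else int(labels.max()) + 1)
    seq = features.central
    if seq.shape[0] != labels.shape[0]:
        raise ValueError(f"{seq.shape[0]} feature rows vs {labels.shape[0]} labels")

    weights = np.ones(K)
    counts = np.bincount(labels, minlength=K)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0)
        warnings.warn(f"classes {missing.tolist()} absent from the train split; "
                      "their weight is set to 0")
        weights[missing] = 0.0
    if class_weights:
        nz = counts > 0
        weights[nz] = counts[nz].sum() / (nz.sum() * counts[nz])

    model = SegmenterModel(seq.shape[1], K, head=head, W=features.W,
                           hidden=hidden, seed=seed)
    model.x_mean = seq.mean(axis=0)
    model.x_std = np.maximum(seq.std(axis=0), 1e-8)
    xin = Tensor((seq - model.x_mean) / model.x_std)
    T = labels.shape[0]
    w_frame = weights[labels]
    w_norm = max(w_frame.sum(), 1e-12)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    rows = np.arange(T)
    for epoch in range(epochs):
        logits = model._forward(xin)                      # (T, K)
        lse = logits.logsumexp(axis=1)
        nll = lse - logits[(rows, labels)]
        loss = (nll * Tensor(w_frame)).sum() / w_norm
        model.zero_grad()
        loss.backward()
        opt.lr = nn.cosine_lr(epoch, epochs, lr)
        opt.step()
    return model


def ensemble_predict(models, features) -> LogitsSeries:
    """Average logits across models, then softmax (pre-softmax ensembling)."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    logits = [m.logits(features) for m in models]
    K = logits[0].shape[1]
    for l in logits:
        if l.shape[1] != K:
            raise ValueError("models disagree on the number of classes")
    per_model = np.stack(logits)
    mean = per_model.mean(axis=0)
    mean = mean - mean.max(axis=1, keepdims=True)
    e = np.exp(mean)
    probs = e / e.sum(axis=1, keepdims=True)
    return LogitsSeries(per_model=per_model, ensemble_probs=probs)


def macro_f1(pred, truth, classes=None) -> float:
    """Unweighted mean of per-class F1 scores.

    ``classes`` restricts scoring to a subset; a requested class absent from
    both prediction and truth is excluded with a warning.
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = truth.labels if isinstance(truth, Ethogram) else np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction length {pred.shape} vs truth {truth.shape}")
    if classes is None:
        classes = np.unique(np.concatenate([pred, truth]))
    f1s = []
    for c in classes:
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        if tp + fp + fn == 0:
            warnings.warn(f"class {c} absent from both prediction and truth; excluded")
            continue
        f1s.append(2.0 * tp / (2.0 * tp + fp + fn))
    if not f1s:
        raise ValueError("no scorable classes")
    return float(np.mean(f1s))
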