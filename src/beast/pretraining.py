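"""Self-supervised pretraining objective and loop.

The objective combines two terms computed from a single masked forward
pass per frame:

* masked autoencoding — a high fraction (default 0.75) of patch tokens is
  hidden, the encoder sees only the visible tokens, zero embeddings are
  inserted at the hidden positions, and a small transformer decoder
  reconstructs pixels under mean squared error;
* temporal InfoNCE — CLS embeddings are nonlinearly projected and each
  anchor's projection is scored against its temporal neighbor (positive)
  versus every other frame in the batch (negatives):

      L = -(2/B) * sum_{i in A} log[ exp(s(i,i')/tau) / sum_{j != i} exp(s(i,j)/tau) ]

  where s is the (optionally L2-normalized) dot product and the denominator
  includes the positive.  The total loss is L_MSE + lambda * L_InfoNCE.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .backbone import EncoderConfig, VisionTransformer
from .video_data import ContrastiveBatch, build_contrastive_batch, patchify, _thumbnail

__all__ = ["MaskPlan", "LossConfig", "TrainState", "TrainingError",
           "make_mask", "mae_loss", "info_nce_loss", "total_loss",
           "masked_forward", "pretrain", "temporal_similarity_auc"]


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class MaskPlan:
    mask: np.ndarray    # (N,) bool, True = masked
    ratio: float
    L: int              # unmasked count

    @property
    def unmasked_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)

    @property
    def masked_idx(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


@dataclasses.dataclass
class LossConfig:
    """Loss settings.

    With ``temperature=1`` and ``normalize_projections=False`` the
    contrastive term is the plain dot-product InfoNCE form; the desk-scale
    defaults below (normalized projections, low temperature, contrastive
    branch on a separate unmasked pass) are what makes the temporal
    objective train within a few hundred steps at this model size — at a
    0.75 mask ratio the sprite is frequently masked out entirely, so a
    masked-pass CLS often cannot carry any temporal signal.
    """

    lam: float = 1.0                 # weight on the contrastive term
    temperature: float = 0.1         # tau; similarity scale
    mse_scope: str = "masked_only"   # or "all_patches"
    normalize_projections: bool = True
    mask_ratio: float = 0.75
    contrastive_full_pass: bool = True  # project CLS of a separate unmasked pass

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"contrastive weight must be >= 0, got {self.lam}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.mse_scope not in ("masked_only", "all_patches"):
            raise ValueError(f"unknown mse_scope {self.mse_scope!r}")


@dataclasses.dataclass
class TrainState:
    step: int
    epoch: int
    lr: float
    seed: int
    loss_history: list


def make_mask(N: int, ratio: float, seed: int) -> MaskPlan:
    """Uniform random mask over N patch positions; L = N - round(ratio*N)."""
    if not (0.0 <= ratio < 1.0):
        raise ValueError(f"mask ratio must be in [0, 1), got {ratio}")
    n_masked = int(round(ratio * N))
    rng = np.random.default_rng(seed)
    masked = rng.choice(N, size=n_masked, replace=False)
    mask = np.zeros(N, dtype=bool)
    mask[masked] = True
    return MaskPlan(mask=mask, ratio=ratio, L=N - n_masked)


def _as_patch_array(x) -> np.ndarray:
    if hasattr(x, "patches"):
        return np.asarray(x.patches)
    return np.asarray(x)


def mae_loss(xp, x_hat, plan, scope: str = "masked_only"):
    """Mean squared reconstruction error.

    ``xp``: target patches, (N, E) or (B, N, E) (PatchGrid accepted);
    ``x_hat``: prediction of the same shape (Tensor or array);
    ``plan``: a MaskPlan or a list of them (one per batch item).

    The error is averaged over the E pixel elements within each patch and
    over the selected patches — all N for ``all_patches``, masked positions
    only for ``masked_only``.  Returns a Tensor if ``x_hat`` is a Tensor,
    else a float.
    """
    target = _as_patch_array(xp)
    tensor_out = isinstance(x_hat, Tensor)
    pred = x_hat if tensor_out else Tensor(np.asarray(x_hat))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs prediction {pred.shape}")
    batched = target.ndim == 3
    plans = plan if isinstance(plan, (list, tuple)) else [plan]
    if scope == "all_patches":
        weights = np.ones(target.shape[:-1])
    elif scope == "masked_only":
        masks = np.stack([p.mask for p in plans])
        weights = masks.astype(float) if batched else masks[0].astype(float)
        if weights.shape != target.shape[:-1]:
            raise ValueError("mask plan does not match patch count")
        if weights.sum() == 0:
            raise ValueError("masked_only scope with an empty mask")
    else:
        raise ValueError(f"unknown mse_scope {scope!r}")
    diff = pred - Tensor(target)
    per_patch = (diff * diff).mean(axis=-1)
    loss = (per_patch * Tensor(weights)).sum() / float(weights.sum())
    return loss if tensor_out else loss.item()


def info_nce_loss(projections, batch: ContrastiveBatch, config: LossConfig | None = None):
    """Temporal InfoNCE over projected CLS embeddings.

    The denominator for anchor i runs over every other batch member j != i,
    including the positive, exactly as in the combined-loss formulation.
    Returns a Tensor if ``projections`` is a Tensor, else a float.
    """
    config = config or LossConfig()
    tensor_out = isinstance(projections, Tensor)
    z = projections if tensor_out else Tensor(np.asarray(projections))
    B = z.shape[0]
    if B != len(batch.frames):
        raise ValueError(f"got {B} projections for a batch of {len(batch.frames)} frames")
    anchors = list(batch.anchors)
    for i in anchors:
        if i not in batch.positive_of:
            raise ValueError(f"anchor {i} has no positive assigned")
    if config.normalize_projections:
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        z = z / norm
    sim = (z @ z.transpose(1, 0)) / config.temperature      # (B, B)
    diag_mask = np.zeros((B, B))
    np.fill_diagonal(diag_mask, -1e30)                      # exclude j = i
    denom = (sim + Tensor(diag_mask)).logsumexp(axis=1)     # (B,)
    a_idx = np.asarray(anchors)
    p_idx = np.asarray([batch.positive_of[i] for i in anchors])
    pos_scores = sim[(a_idx, p_idx)]
    loss = (denom[a_idx] - pos_scores).sum() * (2.0 / B)
    return loss if tensor_out else loss.item()


def total_loss(mse, nce, lam: float):
    """Combined objective: MSE + lambda * InfoNCE."""
    return mse + lam * nce


# --------------------------------------------------------------------- loop

@dataclasses.dataclass
class PretrainResult:
    model: VisionTransformer
    history: pd.DataFrame       # step, mse, nce, total, lr
    state: TrainState


def _gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Per-sample row gather: x (B, N, D), idx (B, L) -> (B, L, D)."""
    b = np.arange(x.shape[0])[:, None]
    return x[(b, idx)]


def masked_forward(model: VisionTransformer, patches: np.ndarray, plans: list):
    """One masked autoencoding pass.

    Tokenizes ``patches`` (B, N, P*P*C), encodes only the visible tokens,
    re-inserts **zero embeddings** at the masked positions to rebuild the
    full-length sequence in original patch order, and decodes it to pixels.

    Returns ``(emb, z_full, recon, token_seq)`` where ``emb`` is the
    FrameEmbedding of the visible pass, ``z_full`` the (B, N, D) decoder
    input and ``recon`` the (B, N, P*P*C) reconstruction.
    """
    cfg = model.config
    B, N = patches.shape[0], cfg.n_patches
    unm_idx = np.stack([p.unmasked_idx for p in plans])
    msk_idx = np.stack([p.masked_idx for p in plans])
    L = plans[0].L
    ts = model.tokenize(patches)
    visible = _gather(ts.tokens, unm_idx)
    emb = model.encode(visible, ts.cls)
    zeros = Tensor(np.zeros((B, N - L, cfg.D)))
    stacked = nn.concat([emb.patch_embeddings, zeros], axis=1)
    perm = np.concatenate([unm_idx, msk_idx], axis=1)
    inv = np.argsort(perm, axis=1)
    z_full = _gather(stacked, inv)
    recon = model.decode(z_full)
    return emb, z_full, recon, ts


def pretrain(videos, encoder: EncoderConfig | VisionTransformer,
             loss: LossConfig | None = None, *, steps: int = 300,
             batch_size: int = 16, min_negative_gap: int = 30,
             base_lr: float = 1e-3, min_lr: float = 0.0, warmup_steps: int = 10,
             weight_decay: float = 0.05, seed: int = 0, augment: bool = False,
             out_dir=None) -> PretrainResult:
    """Run the combined masked-autoencoding + temporal-contrastive loop.

    ``videos``: list of (T, H, W, 3) arrays (or FrameRecord sequences).
    Each step builds a fresh contrastive batch, masks every frame
    independently, reconstructs pixels from the visible tokens, and applies
    one AdamW step under a cosine-annealed learning rate.  Fully seeded.

    By default the CLS embedding fed to the projector comes from the same
    masked pass used for reconstruction (one encoder pass per frame); set
    ``loss.contrastive_full_pass`` for a separate unmasked pass.
    """
    from .video_data import frames_from_array, FrameRecord

    loss_cfg = loss or LossConfig()
    model = encoder if isinstance(encoder, VisionTransformer) else VisionTransformer(encoder)
    cfg = model.config

    seqs = []
    for v, item in enumerate(videos):
        if len(item) and isinstance(item[0], FrameRecord):
            seqs.append(list(item))
        else:
            seqs.append(frames_from_array(np.asarray(item), video_id=f"video_{v}"))
    thumbs = [np.stack([_thumbnail(f.image) for f in s]) for s in seqs]

    # precompute patch arrays per video to avoid re-patchifying every step
    patch_cache = [np.stack([patchify(f.image, cfg.P).patches for f in s]) for s in seqs]
    vid_index = {s[0].video_id: i for i, s in enumerate(seqs)}

    N = cfg.n_patches
    master = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=base_lr, weight_decay=weight_decay)
    history = []
    lr = base_lr
    for step in range(steps):
        step_seed = int(master.integers(2 ** 31))
        batch = build_contrastive_batch(seqs, batch_size, min_negative_gap,
                                        seed=step_seed, thumbnails=thumbs)
        if augment:
            from .video_data import augment_pair
            arng = np.random.default_rng(int(master.integers(2 ** 31)))
            rows = [None] * len(batch.frames)
            for i in batch.anchors:
                j = batch.positive_of[i]
                a_img, p_img = augment_pair(batch.frames[i].image,
                                            batch.frames[j].image, arng)
                rows[i] = patchify(a_img, cfg.P).patches
                rows[j] = patchify(p_img, cfg.P).patches
            patches = np.stack(rows)
        else:
            patches = np.stack([
                patch_cache[vid_index[f.video_id]][f.t] for f in batch.frames])
        B = patches.shape[0]

        plans = [make_mask(N, loss_cfg.mask_ratio, seed=int(master.integers(2 ** 31)))
                 for _ in range(B)]
        emb, _, recon, ts = masked_forward(model, patches, plans)
        mse = mae_loss(patches, recon, plans, scope=loss_cfg.mse_scope)

        if loss_cfg.lam > 0:
            if loss_cfg.contrastive_full_pass:
                full = model.encode(ts.tokens, ts.cls)
                proj = model.project(full.cls_embedding)
            else:
                proj = model.project(emb.cls_embedding)
            nce = info_nce_loss(proj, batch, loss_cfg)
            total = total_loss(mse, nce, loss_cfg.lam)
            nce_val = nce.item()
        else:
            total = mse
            with nn.no_grad():
                proj = model.project(emb.cls_embedding)
                nce_val = info_nce_loss(proj.numpy(), batch, loss_cfg)

        if not np.isfinite(total.item()):
            raise TrainingError(f"non-finite loss at step {step}")

        model.zero_grad()
        total.backward()
        lr = nn.cosine_lr(step, steps, base_lr, min_lr, warmup_steps)
        opt.lr = lr
        opt.step()
        history.append({"step": step, "mse": mse.item(), "nce": nce_val,
                        "total": total.item(), "lr": lr})

    hist = pd.DataFrame(history, columns=["step", "mse", "nce", "total", "lr"])
    state = TrainState(step=steps, epoch=0, lr=lr, seed=seed,
                       loss_history=[h["total"] for h in history])
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save_checkpoint(out / "checkpoint.npz")
        hist.to_csv(out / "loss_history.csv", index=False)
    return PretrainResult(model=model, history=hist, state=state)


def temporal_similarity_auc(model: VisionTransformer, frames: np.ndarray, *,
                            min_gap: int = 30, span: int | None = None,
                            n_negatives: int = 1000, seed: int = 0,
                            normalized: bool = True) -> float:
    """Do projections rank temporal neighbors above distant frames?

    Compares the projected similarity of all (t, t+1) pairs against
    randomly drawn pairs at least ``min_gap`` frames apart, and returns the
    probability that a neighbor pair scores higher (ties count half) — a
    ranking AUC.  ``normalized`` uses cosine similarity, matching the
    similarity the default loss configuration trains; set it False for the
    raw dot-product form.
    """
    span = frames.shape[0] if span is None else min(span, frames.shape[0])
    proj = []
    for s in range(0, span, 50):
        emb = model.embed_frames(np.asarray(frames[s:s + 50], dtype=np.float64))
        proj.append(emb.projection.numpy())
    proj = np.concatenate(proj)
    if normalized:
        proj = proj / (np.linalg.norm(proj, axis=1, keepdims=True) + 1e-12)
    rng = np.random.default_rng(seed)
    pos = np.einsum("ij,ij->i", proj[:-1], proj[1:])
    neg = np.empty(n_negatives)
    for k in range(n_negatives):
        t = int(rng.integers(0, span))
        u = int(rng.integers(0, span))
        while abs(t - u) < min_gap:
            u = int(rng.integers(0, span))
        neg[k] = proj[t] @ proj[u]
    return float((pos[:, None] > neg[None, :]).mean()
                 + 0.5 * (pos[:, None] == neg[None, :]).mean())
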