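"""Vision-transformer backbone: encoder with CLS token, a lightweight
transformer decoder for pixel reconstruction, and a nonlinear projector
producing the vectors used by the contrastive loss.

Patch tokens get fixed 1-D sinusoidal position embeddings; the CLS token is
prepended afterwards and carries no position embedding.  With ``depth=0``
the encoder is an identity stack (useful as an oracle in tests).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["EncoderConfig", "TokenSequence", "FrameEmbedding", "VisionTransformer"]


@dataclasses.dataclass
class EncoderConfig:
    image_size: int = 64
    P: int = 8                  # patch side, pixels
    D: int = 128                # token width
    depth: int = 4
    heads: int = 4
    decoder_width: int = 64
    decoder_depth: int = 2
    projector_hidden: int = 128
    projector_out: int = 128
    channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.image_size % self.P != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch size {self.P}")
        if self.depth > 0 and self.D % self.heads != 0:
            raise ValueError(f"token width {self.D} not divisible by {self.heads} heads")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.P) ** 2

    @property
    def patch_dim(self) -> int:
        return self.P * self.P * self.channels

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TokenSequence:
    """Patch tokens with position embeddings added, plus the CLS token."""

    tokens: Tensor      # (B, N, D)
    cls: Tensor         # (B, 1, D)


@dataclasses.dataclass
class FrameEmbedding:
    patch_embeddings: Tensor   # (B, S, D) — S = N, or L for a masked pass
    cls_embedding: Tensor      # (B, D)
    projection: Tensor | None  # (B, projector_out)


class VisionTransformer(nn.Module):
    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.D
        self.patch_embed = nn.Linear(config.patch_dim, D, rng)
        self.pos_embed = nn.sinusoidal_position_embeddings(config.n_patches, D)
        self.cls_token = Tensor(nn.trunc_normal(rng, (1, 1, D)), requires_grad=True)
        self.blocks = [nn.TransformerBlock(D, config.heads, rng)
                       for _ in range(config.depth)]
        self.norm = nn.LayerNorm(D) if config.depth > 0 else None
        # reconstruction decoder
        dw = config.decoder_width
        self.dec_embed = nn.Linear(D, dw, rng)
        self.dec_pos = nn.sinusoidal_position_embeddings(config.n_patches, dw)
        self.dec_blocks = [nn.TransformerBlock(dw, max(1, config.heads // 2), rng)
                           for _ in range(config.decoder_depth)]
        self.dec_norm = nn.LayerNorm(dw)
        self.dec_head = nn.Linear(dw, config.patch_dim, rng)
        # contrastive projector (2-layer GELU MLP on the CLS embedding)
        self.projector = nn.MLP(D, config.projector_hidden, config.projector_out, rng)

    # ----------------------------------------------------------------- stages
    def tokenize(self, patches) -> TokenSequence:
        """Linear-project flattened patches and add position embeddings.

        ``patches``: (B, N, P*P*C) array or Tensor.
        """
        x = patches if isinstance(patches, Tensor) else Tensor(patches)
        if x.shape[-1] != self.config.patch_dim:
            raise ValueError(
                f"patch dim {x.shape[-1]} does not match config "
                f"P*P*C={self.config.patch_dim}")
        if x.shape[-2] != self.config.n_patches:
            raise ValueError(
                f"patch count {x.shape[-2]} does not match config N={self.config.n_patches}")
        tokens = self.patch_embed(x) + Tensor(self.pos_embed)
        B = x.shape[0]
        cls = self.cls_token * Tensor(np.ones((B, 1, 1)))
        return TokenSequence(tokens=tokens, cls=cls)

    def encode(self, tokens: Tensor, cls: Tensor | None = None) -> FrameEmbedding:
        """Run the encoder over [CLS ; tokens] (tokens may be a masked subset)."""
        if tokens.shape[-1] != self.config.D:
            raise ValueError(
                f"token width {tokens.shape[-1]} does not match config D={self.config.D}")
        if cls is None:
            B = tokens.shape[0]
            cls = self.cls_token * Tensor(np.ones((B, 1, 1)))
        x = nn.concat([cls, tokens], axis=1)
        for blk in self.blocks:
            x = blk(x)
        if self.norm is not None:
            x = self.norm(x)
        cls_out = x[:, 0, :]
        patch_out = x[:, 1:, :]
        return FrameEmbedding(patch_embeddings=patch_out, cls_embedding=cls_out,
                              projection=None)

    def decode(self, z: Tensor) -> Tensor:
        """Reconstruct pixels from the full embedding sequence.

        ``z``: (B, N, D) with zero embeddings at masked positions.
        Returns (B, N, P*P*C).
        """
        if z.shape[-2] != self.config.n_patches:
            raise ValueError(
                f"sequence length {z.shape[-2]} does not match N={self.config.n_patches}")
        x = self.dec_embed(z) + Tensor(self.dec_pos)
        for blk in self.dec_blocks:
            x = blk(x)
        return self.dec_head(self.dec_norm(x))

    def project(self, cls_embedding: Tensor) -> Tensor:
        """Nonlinear projection of CLS embeddings for the contrastive loss."""
        return self.projector(cls_embedding)

    # -------------------------------------------------------------- full pass
    def embed_frames(self, images: np.ndarray, grad: bool = False) -> FrameEmbedding:
        """Full (unmasked) forward pass on a (B, H, W, C) image stack."""
        from .video_data import patchify
        patches = np.stack([patchify(img, self.config.P).patches for img in images])
        if grad:
            ts = self.tokenize(patches)
            emb = self.encode(ts.tokens, ts.cls)
            emb.projection = self.project(emb.cls_embedding)
            return emb
        with nn.no_grad():
            ts = self.tokenize(patches)
            emb = self.encode(ts.tokens, ts.cls)
            emb.projection = self.project(emb.cls_embedding)
        return emb

    # ------------------------------------------------------------ checkpoints
    def save_checkpoint(self, path):
        path = pathlib.Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load_checkpoint(cls, path) -> "VisionTransformer":
        with np.load(pathlib.Path(path)) as data:
            cfg = EncoderConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model
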