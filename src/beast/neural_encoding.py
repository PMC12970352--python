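"""Neural encoding: predict binned neural activity from frame-level features.

Features (CLS embeddings, motion energy, keypoints, or any external series)
are fit to spike counts or to neural principal components with either a
linear reduced-rank regression (RRR) or a nonlinear temporal convolution
network (TCN).  Spike-count predictions are scored in bits per spike (BPS):
the Poisson log-likelihood improvement of the predicted rates over the
per-neuron train-mean rate, normalized by the total test spike count and
log 2, so the mean-rate null scores exactly 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "FeatureSeries", "NeuralBins", "RRRModel", "EncodingScore",
    "extract_cls_features", "motion_energy", "fit_rrr", "fit_tcn_encoder",
    "bits_per_spike", "pc_r2", "time_split", "neural_pcs",
]

RATE_FLOOR = 1e-9


@dataclasses.dataclass
class FeatureSeries:
    X: np.ndarray            # (T, d) aligned to frames
    kind: str = "external"   # cls | motion_energy | keypoints | pca | external

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if not np.isfinite(self.X).all():
            raise ValueError("feature series contains missing or non-finite rows")


@dataclasses.dataclass
class NeuralBins:
    """Spike counts (T, n) or neural PCs (T, k), plus a bin-to-frame map."""

    Y: np.ndarray
    is_counts: bool = True
    bin_to_frame: np.ndarray | None = None   # defaults to identity

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        if self.is_counts:
            if (self.Y < 0).any() or not np.issubdtype(self.Y.dtype, np.integer):
                raise ValueError("spike counts must be non-negative integers")
        if self.bin_to_frame is None:
            self.bin_to_frame = np.arange(self.Y.shape[0])


@dataclasses.dataclass
class EncodingScore:
    per_unit: np.ndarray     # per-neuron BPS or per-PC R^2
    mean: float
    sem: float
    excluded: np.ndarray     # indices of units excluded from the mean


def _score(per_unit: np.ndarray) -> EncodingScore:
    ok = np.isfinite(per_unit)
    vals = per_unit[ok]
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return EncodingScore(per_unit=per_unit, mean=float(vals.mean()), sem=sem,
                         excluded=np.flatnonzero(~ok))


def time_split(T: int, fractions=(0.7, 0.15, 0.15)):
    """Contiguous train/val/test blocks (prevents temporal leakage)."""
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(T * f[0]))
    n_val = int(round(T * f[1]))
    idx = np.arange(T)
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def neural_pcs(counts: np.ndarray, k: int, train_idx=None):
    """Top-k principal components of (optionally train-fit) spike counts."""
    Y = np.asarray(counts, dtype=float)
    fit = Y if train_idx is None else Y[train_idx]
    mu = fit.mean(axis=0)
    _, _, vt = np.linalg.svd(fit - mu, full_matrices=False)
    comps = vt[:k]
    return (Y - mu) @ comps.T, comps, mu


# ------------------------------------------------------------------ features

def extract_cls_features(frames: np.ndarray, model, batch_size: int = 64) -> FeatureSeries:
    """Per-frame CLS embedding of the full (unmasked) forward pass."""
    from .backbone import VisionTransformer
    if not isinstance(model, VisionTransformer):
        model = VisionTransformer.load_checkpoint(model)
    if frames.shape[1] != model.config.image_size:
        raise ValueError(
            f"frame size {frames.shape[1:3]} does not match model resolution "
            f"{model.config.image_size}")
    rows = []
    for start in range(0, frames.shape[0], batch_size):
        emb = model.embed_frames(np.asarray(frames[start:start + batch_size], dtype=np.float64))
        rows.append(emb.cls_embedding.numpy())
    return FeatureSeries(X=np.concatenate(rows, axis=0), kind="cls")


def motion_energy(frames: np.ndarray, crop=None) -> FeatureSeries:
    """Sum of absolute pixel differences between successive frames.

    ``crop`` is an optional (top, bottom, left, right) pixel region.
    ME[0] = 0 by convention.
    """
    f = np.asarray(frames, dtype=float)
    if f.shape[0] < 2:
        raise ValueError("motion energy needs at least 2 frames")
    if crop is not None:
        top, bottom, left, right = crop
        f = f[:, top:bottom, left:right]
        if f.shape[1] == 0 or f.shape[2] == 0:
            raise ValueError(f"empty crop region {crop}")
    me = np.zeros(f.shape[0])
    diffs = np.abs(np.diff(f, axis=0))
    me[1:] = diffs.reshape(f.shape[0] - 1, -1).sum(axis=1)
    return FeatureSeries(X=me[:, None], kind="motion_energy")


# ----------------------------------------------------------------------- RRR

@dataclasses.dataclass
class RRRModel:
    rank: int
    input_proj: np.ndarray    # (d, r)
    output_map: np.ndarray    # (r, n)
    intercept: np.ndarray     # (n,)
    x_mean: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = X.X if isinstance(X, FeatureSeries) else np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.input_proj @ self.output_map + self.intercept

    @property
    def coef(self) -> np.ndarray:
        return self.input_proj @ self.output_map


def fit_rrr(X, Y, rank: int, ridge: float = 0.0) -> RRRModel:
    """Reduced-rank regression: SVD truncation of the ridge OLS solution.

    The full ridge solution B is computed on centered data, the fitted
    values XB are SVD-decomposed, and B is projected onto the top-``rank``
    right singular vectors of the fit.
    """
    X = X.X if isinstance(X, FeatureSeries) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    d, n = X.shape[1], Y.shape[1]
    if rank < 1 or rank > min(d, n):
        raise ValueError(f"rank must be in [1, min(d, n)={min(d, n)}], got {rank}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    gram = Xc.T @ Xc + ridge * np.eye(d)
    try:
        B = np.linalg.solve(gram, Xc.T @ Yc)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular design matrix ({exc}); refit with ridge > 0") from exc
    if ridge == 0.0 and np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            "near-singular design matrix; refit with ridge > 0")
    fitted = Xc @ B
    _, _, vt = np.linalg.svd(fitted, full_matrices=False)
    V = vt[:rank].T                                  # (n, r)
    input_proj = B @ V
    output_map = V.T
    return RRRModel(rank=rank, input_proj=input_proj, output_map=output_map,
                    intercept=y_mean, x_mean=x_mean)


# ----------------------------------------------------------------------- TCN

class TCNEncoder(nn.Module):
    """Two temporal convolutions plus a pointwise head over a centered window.

    The receptive field equals ``window`` (odd).  With Poisson loss the
    output passes through a softplus so predicted rates are positive.
    """

    def __init__(self, d_in: int, d_out: int, window: int = 21, hidden: int = 32,
                 loss: str = "poisson", seed: int = 0):
        if window % 2 == 0 or window < 1:
            raise ValueError(f"window must be odd and positive, got {window}")
        if loss not in ("poisson", "gaussian"):
            raise ValueError(f"unknown loss {loss!r}")
        k1 = window // 2 + 1 if (window // 2) % 2 == 0 else window // 2 + 2
        k2 = window - k1 + 1    # k1 + k2 - 1 == window, both odd
        rng = np.random.default_rng(seed)
        self.loss = loss
        self.window = window
        self.conv1 = nn.Conv1d(d_in, hidden, k1, rng)
        self.conv2 = nn.Conv1d(hidden, hidden, k2, rng)
        self.head = nn.Linear(hidden, d_out, rng)
        self.x_mean = np.zeros(d_in)
        self.x_std = np.ones(d_in)

    def _forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).gelu()
        h = self.conv2(h).gelu()
        return self.head(h)

    def predict(self, X) -> np.ndarray:
        X = X.X if isinstance(X, FeatureSeries) else np.asarray(X, dtype=float)
        with nn.no_grad():
            out = self._forward(Tensor((X - self.x_mean) / self.x_std))
            if self.loss == "poisson":
                out = out.softplus()
        res = out.numpy()
        return np.maximum(res, RATE_FLOOR) if self.loss == "poisson" else res


def _poisson_or_mse(out: Tensor, yt: Tensor, loss: str) -> Tensor:
    if loss == "poisson":
        rate = out.softplus() + RATE_FLOOR
        return (rate - yt * rate.log()).mean()
    diff = out - yt
    return (diff * diff).mean()


def fit_tcn_encoder(X, Y, window: int = 21, hidden: int = 32, seed: int = 0,
                    loss: str = "poisson", epochs: int = 200, lr: float = 5e-3,
                    weight_decay: float = 1e-4, X_val=None, Y_val=None,
                    val_every: int = 10) -> TCNEncoder:
    """Fit the temporal convolution encoder by full-batch AdamW.

    A temporal model with a wide receptive field overfits short recordings
    quickly; when a validation block (``X_val``, ``Y_val``) is supplied the
    fit is checked every ``val_every`` epochs and the parameters with the
    best validation loss are restored at the end.
    """
    X = X.X if isinstance(X, FeatureSeries) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    model = TCNEncoder(X.shape[1], Y.shape[1], window=window, hidden=hidden,
                       loss=loss, seed=seed)
    model.x_mean = X.mean(axis=0)
    model.x_std = np.maximum(X.std(axis=0), 1e-8)
    xin = Tensor((X - model.x_mean) / model.x_std)
    yt = Tensor(Y)
    if X_val is not None:
        X_val = X_val.X if isinstance(X_val, FeatureSeries) else np.asarray(X_val, dtype=float)
        xv = Tensor((X_val - model.x_mean) / model.x_std)
        yv = Tensor(np.asarray(Y_val, dtype=float))
    best_val, best_state = np.inf, None
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    for epoch in range(epochs):
        obj = _poisson_or_mse(model._forward(xin), yt, loss)
        model.zero_grad()
        obj.backward()
        opt.lr = nn.cosine_lr(epoch, epochs, lr)
        opt.step()
        if X_val is not None and (epoch % val_every == 0 or epoch == epochs - 1):
            with nn.no_grad():
                v = _poisson_or_mse(model._forward(xv), yv, loss).item()
            if v < best_val:
                best_val, best_state = v, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


# -------------------------------------------------------------------- scores

def bits_per_spike(pred_rates: np.ndarray, Y: np.ndarray,
                   train_mean: np.ndarray) -> EncodingScore:
    """Per-neuron Poisson bits per spike against the train-mean null.

    BPS_i = [LL(pred_i) - LL(mean_i)] / (total spikes_i * log 2), with
    LL(r) = sum_t (y_t log r_t - r_t).  Neurons with zero test spikes are
    excluded (NaN in ``per_unit``, listed in ``excluded``).
    """
    pred = np.asarray(pred_rates, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mean_rate = np.broadcast_to(np.asarray(train_mean, dtype=float), pred.shape)
    if (pred <= 0).any():
        raise ValueError("predicted rates must be positive; apply a rate floor "
                         f"(e.g. {RATE_FLOOR}) before scoring")
    if (mean_rate <= 0).any():
        raise ValueError("train-mean rates must be positive for scored neurons")
    ll_pred = (Y * np.log(pred) - pred).sum(axis=0)
    ll_null = (Y * np.log(mean_rate) - mean_rate).sum(axis=0)
    n_spikes = Y.sum(axis=0)
    per = np.full(Y.shape[1], np.nan)
    nz = n_spikes > 0
    per[nz] = (ll_pred[nz] - ll_null[nz]) / (n_spikes[nz] * np.log(2.0))
    return _score(per)


def pc_r2(pred: np.ndarray, Yc: np.ndarray) -> EncodingScore:
    """Per-component R^2 = 1 - SSE/SST, SST about the test mean."""
    pred = np.asarray(pred, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if pred.shape != Yc.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {Yc.shape}")
    sse = ((Yc - pred) ** 2).sum(axis=0)
    sst = ((Yc - Yc.mean(axis=0)) ** 2).sum(axis=0)
    per = np.full(Yc.shape[1], np.nan)
    ok = sst > 0
    per[ok] = 1.0 - sse[ok] / sst[ok]
    return _score(per)
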