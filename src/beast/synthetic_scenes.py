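"""Synthetic behavioral-scene generator.

Emulates the data regime the pretraining framework targets: a static
background with a single moving articulated sprite, hidden-Markov behavioral
states that modulate the sprite's motion statistics, and Poisson spike
counts driven by the sprite's kinematics.  Every downstream stage (masked
autoencoding, temporal contrastive learning, neural encoding, pose
estimation, action segmentation) can therefore be exercised against known
ground truth without external data.

Conventions: image origin top-left, x rightward, y downward, 0-based pixels;
frame indexing 0-based.
"""

from __future__ import annotations

import dataclasses
import pathlib

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

__all__ = ["SceneConfig", "SceneSample", "SceneConfigError",
           "generate_scene", "write_scene", "read_scene"]


class SceneConfigError(ValueError):
    """Raised when a scene configuration violates an invariant."""


@dataclasses.dataclass
class SceneConfig:
    """Parameters of the synthetic behavioral scene.

    The sprite follows a mean-reverting (Ornstein-Uhlenbeck-style) random
    walk; behavioral states scale the step standard deviation, so states
    are defined by *motion*, not appearance, and recovering them requires
    temporal context.
    """

    image_height: int = 64
    image_width: int = 64
    n_frames: int = 500
    background_seed: int = 0
    appearance_seed: int = 0   # sprite geometry; fixed across "animals" of a setup
    sprite_radius: float = 8.0
    n_keypoints: int = 4
    motion_reversion: float = 0.05   # pull toward frame center, per frame
    motion_step_sd: float = 2.5      # base step s.d. in pixels
    n_states: int = 3
    transition_matrix: np.ndarray | None = None   # defaults to sticky chain
    state_step_multipliers: np.ndarray | None = None  # defaults to geometric spread
    n_neurons: int = 12
    readout_scale: float = 1.0
    bin_rate_max: float = 5.0        # expected spikes per bin, ceiling
    keypoint_jitter_sd: float = 0.5  # pixels; known floor on pose error
    seed: int = 0

    def __post_init__(self):
        if self.transition_matrix is None:
            # sticky chain: 0.95 self-transition, rest spread uniformly
            K = self.n_states
            tm = np.full((K, K), 0.05 / max(K - 1, 1))
            np.fill_diagonal(tm, 0.95 if K > 1 else 1.0)
            self.transition_matrix = tm
        else:
            self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.state_step_multipliers is None:
            # well-separated per-state motion scales (0.25x, 1x, 4x, ...)
            self.state_step_multipliers = 4.0 ** (
                np.arange(self.n_states) - (self.n_states - 1) / 2.0
            )
        else:
            self.state_step_multipliers = np.asarray(self.state_step_multipliers, dtype=float)
        self.validate()

    def validate(self):
        for field in ("image_height", "image_width", "n_frames", "n_keypoints",
                      "n_states", "n_neurons"):
            if getattr(self, field) <= 0:
                raise SceneConfigError(f"{field} must be positive, got {getattr(self, field)}")
        if self.sprite_radius >= min(self.image_height, self.image_width) / 4:
            raise SceneConfigError(
                "sprite_radius must be below min(image_height, image_width)/4, "
                f"got sprite_radius={self.sprite_radius}"
            )
        tm = self.transition_matrix
        if tm.shape != (self.n_states, self.n_states):
            raise SceneConfigError(
                f"transition_matrix shape {tm.shape} does not match n_states={self.n_states}"
            )
        if np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9 or (tm < 0).any():
            raise SceneConfigError("transition_matrix rows must be non-negative and sum to 1")
        if self.state_step_multipliers.shape != (self.n_states,):
            raise SceneConfigError("state_step_multipliers length must equal n_states")
        if self.motion_step_sd < 0 or self.keypoint_jitter_sd < 0:
            raise SceneConfigError("motion_step_sd and keypoint_jitter_sd must be non-negative")
        if self.bin_rate_max <= 0:
            raise SceneConfigError(f"bin_rate_max must be positive, got {self.bin_rate_max}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        d["state_step_multipliers"] = self.state_step_multipliers.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


@dataclasses.dataclass
class SceneSample:
    """A generated scene with full ground truth.

    frames     : (n_frames, H, W, 3) float32 in [0, 1]
    keypoints  : (n_frames, n_keypoints, 2) pixel (x, y)
    states     : (n_frames,) int behavioral labels
    spikes     : (n_frames, n_neurons) non-negative integer counts
    rates      : (n_frames, n_neurons) generating Poisson rates (ground truth)
    positions  : (n_frames, 2) sprite-center (x, y)
    config     : the SceneConfig that produced the sample
    """

    frames: np.ndarray
    keypoints: np.ndarray
    states: np.ndarray
    spikes: np.ndarray
    rates: np.ndarray
    positions: np.ndarray
    config: SceneConfig


def _render_background(cfg: SceneConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.background_seed)
    noise = rng.uniform(size=(cfg.image_height, cfg.image_width))
    bg = gaussian_filter(noise, sigma=3.0)
    bg = (bg - bg.min()) / max(np.ptp(bg), 1e-12)
    return 0.15 + 0.25 * bg   # dim, low-contrast backdrop


def generate_scene(config: SceneConfig) -> SceneSample:
    """Simulate a scene; deterministic for a fixed ``config.seed``."""
    config.validate()
    cfg = config
    H, W, T = cfg.image_height, cfg.image_width, cfg.n_frames
    rng = np.random.default_rng(cfg.seed)

    # hidden-Markov behavioral states
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.integers(cfg.n_states)
    for t in range(1, T):
        states[t] = rng.choice(cfg.n_states, p=cfg.transition_matrix[states[t - 1]])

    # mean-reverting sprite walk, state-scaled step s.d., clamped to margins
    margin = cfg.sprite_radius + 1.0
    center = np.array([W / 2.0, H / 2.0])
    pos = np.empty((T, 2))
    pos[0] = center
    for t in range(1, T):
        step = cfg.motion_step_sd * cfg.state_step_multipliers[states[t]] * rng.standard_normal(2)
        nxt = pos[t - 1] + cfg.motion_reversion * (center - pos[t - 1]) + step
        pos[t] = np.clip(nxt, [margin, margin], [W - 1 - margin, H - 1 - margin])

    # rigid keypoint offsets inside the sprite, plus small isotropic jitter;
    # geometry comes from appearance_seed so scenes that differ only in
    # `seed` show the same subject with new behavior (a held-out animal
    # from the same setup)
    geom_rng = np.random.default_rng(cfg.appearance_seed)
    angles = 2.0 * np.pi * np.arange(cfg.n_keypoints) / cfg.n_keypoints
    radii = cfg.sprite_radius * (0.4 + 0.35 * geom_rng.uniform(size=cfg.n_keypoints))
    offsets = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    jitter = cfg.keypoint_jitter_sd * rng.standard_normal((T, cfg.n_keypoints, 2))
    keypoints = pos[:, None, :] + offsets[None, :, :] + jitter
    keypoints[..., 0] = np.clip(keypoints[..., 0], 0, W - 1)
    keypoints[..., 1] = np.clip(keypoints[..., 1], 0, H - 1)

    # render: static background + bright sprite blob + keypoint dots
    bg = _render_background(cfg)
    xs, ys = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    frames = np.empty((T, H, W, 3), dtype=np.float32)
    sigma_blob = cfg.sprite_radius / 2.0
    for t in range(T):
        d2 = (xs - pos[t, 0]) ** 2 + (ys - pos[t, 1]) ** 2
        img = bg + 0.55 * np.exp(-d2 / (2.0 * sigma_blob ** 2))
        for k in range(cfg.n_keypoints):
            dk2 = (xs - keypoints[t, k, 0]) ** 2 + (ys - keypoints[t, k, 1]) ** 2
            img = img + 0.35 * np.exp(-dk2 / (2.0 * 1.2 ** 2))
        frames[t] = np.clip(img, 0.0, 1.0)[..., None].astype(np.float32)

    # Poisson spikes from a softplus readout of [position, velocity]
    vel = np.diff(pos, axis=0, prepend=pos[:1])
    feats = np.column_stack([
        (pos[:, 0] - W / 2.0) / (W / 2.0),
        (pos[:, 1] - H / 2.0) / (H / 2.0),
        vel[:, 0] / max(cfg.motion_step_sd, 1e-9),
        vel[:, 1] / max(cfg.motion_step_sd, 1e-9),
    ])
    w_read = cfg.readout_scale * rng.standard_normal((feats.shape[1], cfg.n_neurons))
    b_read = 0.5 * rng.standard_normal(cfg.n_neurons)
    drive = feats @ w_read + b_read
    rates = np.logaddexp(0.0, drive)             # softplus
    rates *= cfg.bin_rate_max / max(rates.max(), 1e-12)
    rates = np.maximum(rates, 1e-9)
    spikes = rng.poisson(rates).astype(np.int64)

    return SceneSample(frames=frames, keypoints=keypoints, states=states,
                       spikes=spikes, rates=rates, positions=pos, config=cfg)


def write_scene(sample: SceneSample, out_dir) -> pathlib.Path:
    """Write frames as PNG plus CSV tables; return the manifest path."""
    out = pathlib.Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create scene directory {out}: {exc}") from exc

    frame_dir = out / "frames"
    frame_dir.mkdir(exist_ok=True)
    T = sample.frames.shape[0]
    frame_files = []
    for t in range(T):
        name = f"frame_{t:06d}.png"
        iio.imwrite(frame_dir / name, (sample.frames[t] * 255.0 + 0.5).astype(np.uint8))
        frame_files.append(f"frames/{name}")

    K = sample.keypoints.shape[1]
    kp = pd.DataFrame({
        "frame": np.repeat(np.arange(T), K),
        "kp_index": np.tile(np.arange(K), T),
        "x": sample.keypoints[..., 0].ravel(),
        "y": sample.keypoints[..., 1].ravel(),
    })
    kp.to_csv(out / "keypoints.csv", index=False)

    pd.DataFrame({"frame": np.arange(T), "label": sample.states}).to_csv(
        out / "states.csv", index=False)

    spikes = pd.DataFrame(
        sample.spikes, columns=[f"neuron_{i}" for i in range(sample.spikes.shape[1])])
    spikes.insert(0, "frame", np.arange(T))
    spikes.to_csv(out / "spikes.csv", index=False)

    manifest = {
        "config": sample.config.to_dict(),
        "frames": frame_files,
        "keypoints": "keypoints.csv",
        "states": "states.csv",
        "spikes": "spikes.csv",
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_scene(scene_dir):
    """Read back what :func:`write_scene` wrote.

    Returns (frames, keypoints, states, spikes, config); frames are float32
    in [0, 1] (8-bit quantized relative to the generated sample).
    """
    d = pathlib.Path(scene_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    cfg = SceneConfig.from_dict(manifest["config"])
    frames = np.stack([
        np.asarray(iio.imread(d / rel), dtype=np.float32) / 255.0
        for rel in manifest["frames"]
    ])
    kp = pd.read_csv(d / manifest["keypoints"])
    T = frames.shape[0]
    K = kp["kp_index"].max() + 1
    keypoints = np.empty((T, K, 2))
    keypoints[kp["frame"], kp["kp_index"], 0] = kp["x"]
    keypoints[kp["frame"], kp["kp_index"], 1] = kp["y"]
    states = pd.read_csv(d / manifest["states"])["label"].to_numpy()
    spikes_df = pd.read_csv(d / manifest["spikes"])
    spikes = spikes_df.drop(columns="frame").to_numpy()
    return frames, keypoints, states, spikes, cfg
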