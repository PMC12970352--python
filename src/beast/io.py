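"""Readers and writers for the tabular side-car formats.

Keypoint tables: CSV with columns ``frame, kp_index (or kp_name), x, y``
and optional ``visible``.  Ethograms: CSV with ``frame, label``.  Neural
bins: CSV with ``frame, neuron_0..`` or an HDF5 file with a ``counts``
dataset (time-bins x neurons).
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd

from .action_segmentation import Ethogram
from .neural_encoding import NeuralBins
from .pose_estimation import KeypointLabels

__all__ = ["read_keypoint_csv", "write_keypoint_csv", "read_ethogram_csv",
           "write_ethogram_csv", "read_neural_bins"]


def read_keypoint_csv(path) -> tuple[np.ndarray, KeypointLabels]:
    """Returns (frame indices, KeypointLabels) from a long-format CSV."""
    df = pd.read_csv(path)
    key = "kp_index" if "kp_index" in df.columns else "kp_name"
    kp_ids = {k: i for i, k in enumerate(sorted(df[key].unique(), key=str))}
    frames = np.sort(df["frame"].unique())
    frame_pos = {f: i for i, f in enumerate(frames)}
    K = len(kp_ids)
    kps = np.full((len(frames), K, 2), np.nan)
    vis = np.zeros((len(frames), K), dtype=bool)
    for _, row in df.iterrows():
        i, k = frame_pos[row["frame"]], kp_ids[row[key]]
        kps[i, k] = (row["x"], row["y"])
        vis[i, k] = bool(row.get("visible", True))
    kps = np.nan_to_num(kps, nan=0.0)
    return frames, KeypointLabels(keypoints=kps, visibility=vis)


def write_keypoint_csv(path, frames, labels: KeypointLabels, confidence=None):
    rows = []
    F, K, _ = labels.keypoints.shape
    for i in range(F):
        for k in range(K):
            row = {"frame": int(frames[i]), "kp_index": k,
                   "x": labels.keypoints[i, k, 0], "y": labels.keypoints[i, k, 1],
                   "visible": bool(labels.visibility[i, k])}
            if confidence is not None:
                row["confidence"] = confidence[i, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ethogram_csv(path) -> Ethogram:
    df = pd.read_csv(path).sort_values("frame")
    return Ethogram(labels=df["label"].to_numpy())


def write_ethogram_csv(path, ethogram: Ethogram):
    pd.DataFrame({"frame": np.arange(len(ethogram.labels)),
                  "label": ethogram.labels}).to_csv(path, index=False)


def read_neural_bins(path) -> NeuralBins:
    """Read binned spike counts from CSV (``frame, neuron_*``) or HDF5."""
    p = pathlib.Path(path)
    if p.suffix in (".h5", ".hdf5"):
        with h5py.File(p, "r") as f:
            counts = np.asarray(f["counts"], dtype=np.int64)
            b2f = np.asarray(f["bin_to_frame"]) if "bin_to_frame" in f else None
        return NeuralBins(Y=counts, is_counts=True, bin_to_frame=b2f)
    df = pd.read_csv(p)
    cols = [c for c in df.columns if c != "frame"]
    return NeuralBins(Y=df[cols].to_numpy(dtype=np.int64), is_counts=True,
                      bin_to_frame=df["frame"].to_numpy() if "frame" in df.columns else None)
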