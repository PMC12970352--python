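"""Generate a synthetic behavioral scene and inspect its ground truth.

The scene emulates a controlled behavior experiment: a static background,
one moving articulated sprite (the "animal") whose motion statistics switch
with hidden behavioral states, and Poisson spike counts driven by the
sprite's position and velocity.
"""

import numpy as np

from beast import SceneConfig, generate_scene, write_scene

config = SceneConfig(n_frames=300, n_states=3, n_neurons=12, seed=42)
scene = generate_scene(config)

print(f"frames    : {scene.frames.shape}  (values in [{scene.frames.min():.2f}, "
      f"{scene.frames.max():.2f}])")
print(f"keypoints : {scene.keypoints.shape}  (pixel x, y per keypoint)")
print(f"states    : {scene.states.shape}, occupancy "
      f"{np.bincount(scene.states, minlength=3) / len(scene.states)}")
print(f"spikes    : {scene.spikes.shape}, mean rate "
      f"{scene.spikes.mean():.2f} per bin")

# per-state speed statistics — states differ in motion, not appearance
speed = np.linalg.norm(np.diff(scene.positions, axis=0), axis=1)
for k in range(3):
    sel = scene.states[1:] == k
    print(f"state {k}: mean speed {speed[sel].mean():6.2f} px/frame "
          f"({sel.mean() * 100:.0f}% of frames)")

manifest = write_scene(scene, "scratch/example_scene")
print(f"\nwrote PNG frames + CSV tables; manifest: {manifest}")
print("The per-state speeds differ by ~4x steps — that separation is what "
      "makes behavioral states recoverable from temporal context alone.")
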