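"""Action segmentation from a frozen backbone.

Patch embeddings are attention-pooled into frame vectors, enriched with
inter-frame differences, and classified by a small temporal convolution
head; five seeds are ensembled by averaging logits before the softmax.
Scoring is macro-averaged F1 on a *held-out scene* (same generator
configuration, new seed — the synthetic analog of a held-out animal).
"""

import numpy as np

from beast import (SceneConfig, generate_scene, pretrain, Ethogram,
                   pool_video_features, build_windows, train_segmenter,
                   ensemble_predict, macro_f1)
from beast.backbone import EncoderConfig
from beast.pretraining import LossConfig

train_scene = generate_scene(SceneConfig(n_frames=900, seed=31))
test_scene = generate_scene(SceneConfig(n_frames=400, seed=41))

print("pretraining backbone (60 steps, small demo budget)...")
res = pretrain([train_scene.frames], EncoderConfig(seed=0), LossConfig(),
               steps=60, batch_size=16, seed=0)

f_tr = pool_video_features(train_scene.frames, res.model, source="patch", seed=0)
f_te = pool_video_features(test_scene.frames, res.model, source="patch", seed=0)
w_tr, w_te = build_windows(f_tr, 11), build_windows(f_te, 11)

models = [train_segmenter(w_tr, Ethogram(train_scene.states), head="tcn",
                          seed=s, epochs=150) for s in range(5)]
ens = ensemble_predict(models, w_te)
pred = ens.ensemble_probs.argmax(axis=1)

f1 = macro_f1(pred, test_scene.states)
singles = [macro_f1(m.predict(w_te), test_scene.states) for m in models]
print(f"single-seed macro-F1: {np.mean(singles):.3f} "
      f"(range {min(singles):.3f}-{max(singles):.3f})")
print(f"5-seed ensemble F1  : {f1:.3f}   (chance for 3 states: 0.333)")
print("\nStates differ only in motion statistics, so beating chance requires "
      "temporal context — the inter-frame differences and the TCN window "
      "supply it.")
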