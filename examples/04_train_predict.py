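"""Train a miniature model on synthetic B-scans and measure held-out accuracy.

A deliberately tiny setup (48 x 48 B-scans, a narrow network, 10 epochs) so
the script finishes in a few minutes on a laptop CPU; the full reduced-scale
experiment lives in the test suite.
"""

import numpy as np

from octlayers import SyntheticConfig, build_model, generate_bscan, normalize, train
from octlayers.backbone import ArchitectureConfig, DilationBlockSpec
from octlayers.training import TrainingConfig, TrainingSample

sim = SyntheticConfig(height=48, width=48, base_bm_row=30.0, bm_curve_amplitude=2.0,
                      bm_tilt=1.0, rpe_offset=7.0, ez_offset=5.0, vertical_jitter=3.0,
                      druse_amplitude=(3.0, 6.0), druse_sigma_x=(3.0, 6.0))
gen = np.random.default_rng(0)

def samples(n):
    return [TrainingSample(image=s.images[0], heights=s.heights[0].astype(np.float32),
                           annotation=s.annotation[0])
            for s in (generate_bscan(sim, gen) for _ in range(n))]

train_set, test_set = samples(100), samples(16)

arch = ArchitectureConfig(init_channels=(4, 8, 16), feature_width=16,
                          attention_channels=16,
                          dilation_blocks=(DilationBlockSpec(8, 1, 3),
                                           DilationBlockSpec(8, 2, 6),
                                           DilationBlockSpec(8, 4, 12)),
                          n_output_layers=3)
model = build_model(arch, seed=0)
tcfg = TrainingConfig(epochs=10, center_offset_above_bm=8.0, vshift_range=4, seed=0)
result = train(model, train_set, tcfg)
print("per-epoch train SSE/B-scan:",
      [f"{v:.0f}" for v in result.history["train_sse"]])

errs = []
for s in test_set:
    pred = model.forward(normalize(s.image)[None, None], training=False)[0]
    errs.append(np.abs(np.round(pred) - s.heights))
mae = np.stack(errs).mean(axis=(0, 2))
print(f"held-out MAE (EZ, RPE, BM): {np.round(mae, 2)} px")
# The loss is a *sum* over annotated A-scans, so partially annotated B-scans
# would weigh less; here every column is annotated.
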