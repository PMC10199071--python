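"""Quantify drusen from layer heights and compare with the planted truth.

Runs the full pipeline — rectification, histogram-mode healthy-RPE offset,
voxelization, en-face component filtering — on a synthetic volume's exact
heights.
"""

import numpy as np

from octlayers import SyntheticConfig, dice, generate_volume, quantify_drusen

cfg = SyntheticConfig(n_bscans=16, drusen_per_bscan=2.0)
vol = generate_volume(cfg, np.random.default_rng(3))

result = quantify_drusen(vol.heights[:, 1], vol.heights[:, 2],
                         height=cfg.height, spacing=cfg.spacing)
print(f"healthy RPE offset: {result.offset.d:.2f} px  (planted: {cfg.rpe_offset})")
print(f"drusen voxels: {result.voxel_count}, volume: {result.volume_um3:.0f} um^3")
print(f"dice vs ground truth: {dice(result.mask.voxels, vol.drusen):.3f}")
print(f"en-face projection peak height: {result.enface.max()} px")
# Residual disagreement is voxel discretization plus the sub-bin error of the
# offset estimate; components shallower than 2 px were removed as false
# positives.
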