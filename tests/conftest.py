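import numpy as np
import pytest

from octlayers.backbone import ArchitectureConfig, DilationBlockSpec, build_model
from octlayers.synthetic import SyntheticConfig, generate_bscan
from octlayers.training import TrainingSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_arch():
    """A miniature architecture for fast construction and forward passes."""
    return ArchitectureConfig(
        init_channels=(2, 3, 4),
        feature_width=4,
        attention_channels=4,
        dilation_blocks=(DilationBlockSpec(3, 1, 2), DilationBlockSpec(3, 2, 4)),
        n_output_layers=3,
    )


@pytest.fixture
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=0)


@pytest.fixture
def small_sim_config():
    """Small, fast synthetic geometry (64 x 64) with deterministic layers."""
    return SyntheticConfig(
        height=64, width=64, base_bm_row=40.0, bm_tilt=2.0,
        bm_curve_amplitude=3.0, rpe_offset=8.0, ez_offset=6.0,
        druse_amplitude=(3.0, 8.0), druse_sigma_x=(3.0, 6.0),
        vertical_jitter=4.0,
    )


def make_training_samples(cfg: SyntheticConfig, n: int, seed: int) -> list[TrainingSample]:
    gen = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = generate_bscan(cfg, gen)
        out.append(TrainingSample(
            image=s.images[0],
            heights=s.heights[0].astype(np.float32),
            annotation=s.annotation[0],
        ))
    return out
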